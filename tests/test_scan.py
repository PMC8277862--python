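"""Candidate detection, filters, TSD calling and family grouping."""


import pytest

from packtir.io import ConsensusTE, GeneModel, GenomeSequence, TEAnnotationRecord
from packtir.scan import (PackTIRCandidate, ParentHit, ScanParams, TSDCall,
                          apply_confound_filters, assign_parent, detect_tsd,
                          find_flanked_candidates, group_into_families,
                          run_scan, validate_pass_set)
from packtir.simulate import SimulationConfig, plant_genome

from tests.conftest import random_dna


def _flanking_pair(chrom, left_span, right_span, cons="TE1", strand="+", L=60):
    """Two annotation rows covering the full consensus on each side."""
    return [
        TEAnnotationRecord(chrom, *left_span, strand, cons,
                           cons_start=1, cons_end=L),
        TEAnnotationRecord(chrom, *right_span, strand, cons,
                           cons_start=1, cons_end=L),
    ]


@pytest.fixture()
def toy(rng):
    g = random_dna(rng, 4000)
    cons = random_dna(rng, 60)
    genome = {"chr1": GenomeSequence("chr1", g)}
    lib = {"TE1": ConsensusTE("TE1", cons)}
    return genome, lib


class TestFlankedCandidates:
    def test_empty_annotation(self, toy):
        genome, lib = toy
        assert find_flanked_candidates([], genome, lib) == []

    def test_gap_of_exactly_100_rejected(self, toy):
        genome, lib = toy
        ann = _flanking_pair("chr1", (500, 560), (660, 720))
        assert find_flanked_candidates(ann, genome, lib) == []

    def test_gap_of_101_accepted(self, toy):
        genome, lib = toy
        ann = _flanking_pair("chr1", (500, 560), (661, 721))
        (cand,) = find_flanked_candidates(ann, genome, lib)
        assert cand.internal_span == (560, 661)
        assert len(cand.internal_seq) == 101

    def test_terminal_coverage_required(self, toy):
        genome, lib = toy
        ann = _flanking_pair("chr1", (500, 560), (661, 721))
        ann[1].cons_start, ann[1].cons_end = 1, 40   # right arm misses 3' end
        assert find_flanked_candidates(ann, genome, lib) == []
        # covering through [L-10+1, L] restores the candidate
        ann[1].cons_start, ann[1].cons_end = 45, 60
        assert len(find_flanked_candidates(ann, genome, lib)) == 1

    def test_te_in_internal_gap_rejected(self, toy):
        genome, lib = toy
        ann = _flanking_pair("chr1", (500, 560), (861, 921))
        ann.append(TEAnnotationRecord("chr1", 600, 700, "+", "OTHER"))
        assert find_flanked_candidates(ann, genome, lib) == []

    def test_missing_consensus_filtered_not_crash(self, toy):
        genome, _ = toy
        ann = _flanking_pair("chr1", (500, 560), (661, 721), cons="GHOST")
        (cand,) = find_flanked_candidates(ann, genome, {})
        assert cand.status == "filtered:no_consensus"

    def test_opposite_strand_pair_rejected_by_default(self, toy):
        genome, lib = toy
        ann = _flanking_pair("chr1", (500, 560), (661, 721))
        ann[1].strand = "-"
        assert find_flanked_candidates(ann, genome, lib) == []
        params = ScanParams(require_same_orientation=False)
        assert len(find_flanked_candidates(ann, genome, lib, params)) == 1

    def test_mismatched_linkage_ids_rejected(self, toy):
        genome, lib = toy
        ann = _flanking_pair("chr1", (500, 560), (661, 721))
        ann[0].linkage_id, ann[1].linkage_id = 1, 2
        assert find_flanked_candidates(ann, genome, lib) == []


class TestAssignParent:
    def _candidate_with_copies(self, rng, n_external):
        """Genome with the internal sequence at the candidate plus
        ``n_external`` exact copies elsewhere."""
        cons = random_dna(rng, 60)
        internal = random_dna(rng, 150)
        left, right = cons, cons
        chrom = (random_dna(rng, 500) + left + internal + right
                 + random_dna(rng, 500))
        for _ in range(n_external):
            chrom += internal + random_dna(rng, 300)
        genome = {"chr1": GenomeSequence("chr1", chrom)}
        ann = _flanking_pair("chr1", (500, 560), (710, 770))
        lib = {"TE1": ConsensusTE("TE1", cons)}
        (cand,) = find_flanked_candidates(ann, genome, lib)
        return cand, genome

    def test_single_external_copy_passes(self, rng):
        cand, genome = self._candidate_with_copies(rng, 1)
        assign_parent(cand, genome, ScanParams(parent_min_score=100))
        assert cand.status == "pass"
        assert cand.parent.hit.target_span[0] >= 1270
        assert cand.parent.len_ratio == pytest.approx(1.0)

    def test_two_equal_external_copies_ambiguous(self, rng):
        cand, genome = self._candidate_with_copies(rng, 2)
        assign_parent(cand, genome, ScanParams(parent_min_score=100))
        assert cand.status == "filtered:ambiguous_parent"

    def test_no_external_copy_filtered(self, rng):
        cand, genome = self._candidate_with_copies(rng, 0)
        assign_parent(cand, genome, ScanParams(parent_min_score=100))
        assert cand.status == "filtered:no_parent"

    def test_relaxed_mode_waives_parent(self, rng):
        cand, genome = self._candidate_with_copies(rng, 0)
        assign_parent(cand, genome, ScanParams(relaxed_parent=True))
        assert cand.status == "pass_relaxed"

    def test_diverged_parent_recovered(self, small_config):
        """A planted parent with 5% capture divergence still passes at
        identity >= 90."""
        cfg = SimulationConfig(genome_len=120_000, n_te_copies=10,
                               n_packtirs=4, n_multicopy_families=0,
                               capture_divergence=0.05)
        genome, ann, genes, lib, truths = plant_genome(cfg, seed=23)
        libmap = {c.name: c for c in lib}
        cands, _ = run_scan(ann, genome, libmap, genes)
        passed = [c for c in cands if c.passed]
        assert passed, "diverged captures must still be recovered"
        for c in passed:
            assert c.parent.hit.identity_pct >= 90


class TestConfoundFilters:
    def _passing_candidate(self, rng, parent_at=2000, parent_len=150):
        cons = random_dna(rng, 60)
        internal = random_dna(rng, parent_len)
        chrom = list(random_dna(rng, 4000))
        chrom[500:560] = cons
        chrom[560:560 + parent_len] = internal
        chrom[560 + parent_len:620 + parent_len] = cons
        chrom[parent_at:parent_at + parent_len] = internal
        genome = {"chr1": GenomeSequence("chr1", "".join(chrom))}
        ann = _flanking_pair("chr1", (500, 560),
                             (560 + parent_len, 620 + parent_len))
        lib = {"TE1": ConsensusTE("TE1", cons)}
        (cand,) = find_flanked_candidates(ann, genome, lib)
        assign_parent(cand, genome, ScanParams(parent_min_score=100))
        assert cand.status == "pass"
        return cand, genome, ann

    def test_te_in_parent_flank_filters_segdup(self, rng):
        cand, genome, ann = self._passing_candidate(rng)
        ps = cand.parent.hit.target_span[0]
        ann = ann + [TEAnnotationRecord("chr1", ps - 60, ps - 50, "+", "TEX")]
        apply_confound_filters(cand, ann, [])
        assert cand.status == "filtered:segdup_flank_te"

    def test_clean_parent_flanks_keep_pass(self, rng):
        cand, genome, ann = self._passing_candidate(rng)
        apply_confound_filters(cand, [], [])
        assert cand.status == "pass"

    def test_monoexonic_gene_not_retroduplicate(self, rng):
        cand, genome, ann = self._passing_candidate(rng)
        ps, pe = cand.parent.hit.target_span
        gm = GeneModel("g1", "g1.t1", "chr1", "+", [(ps, pe)])
        from packtir.scan import attach_parent_seq
        attach_parent_seq(cand, genome)
        apply_confound_filters(cand, [], [gm])
        assert cand.status == "pass"

    def test_simulated_retrocopy_filtered(self):
        """A planted intronless capture of a two-exon gene is excluded."""
        cfg = SimulationConfig(genome_len=150_000, n_te_copies=8,
                               n_packtirs=2, n_multicopy_families=0,
                               n_retro_confounds=2)
        genome, ann, genes, lib, truths = plant_genome(cfg, seed=31)
        libmap = {c.name: c for c in lib}
        cands, _ = run_scan(ann, genome, libmap, genes)
        retro_loci = {(t.chrom, t.start, t.end) for t in truths
                      if t.type == "retro_confound"}
        assert retro_loci
        statuses = {(c.chrom, *c.element_span): c.status for c in cands}
        for locus in retro_loci:
            assert statuses.get(locus) == "filtered:retroduplicate", \
                (locus, statuses.get(locus))


class TestDetectTSD:
    def _cand(self, chrom_seq, es, ee):
        left = TEAnnotationRecord("c", es, es + 10, "+", "TE1")
        right = TEAnnotationRecord("c", ee - 10, ee, "+", "TE1")
        return PackTIRCandidate(
            "X", "c", left, right, (es + 10, ee - 10), "",
            ConsensusTE("TE1", "A" * 30)), \
            {"c": GenomeSequence("c", chrom_seq)}

    def test_reference_tsd_example(self):
        # ...GG TACATATATG [element] TACATATATG CC...
        elem = "CCCCGGGGCCCCGGGGCCCC"
        seq = "GGGGGGATTTGG" + "TACATATATG" + elem + "TACATATATG" + "CCTTTTTTTT"
        es = len("GGGGGGATTTGGTACATATATG")
        cand, genome = self._cand(seq, es, es + len(elem))
        call = detect_tsd(cand, genome)
        assert call is not None
        assert call.seq == "TACATATATG"
        assert call.length == 10

    def test_no_shared_flank_gives_absent(self):
        seq = "A" * 30 + "G" * 20 + "C" * 30
        cand, genome = self._cand(seq, 30, 50)
        assert detect_tsd(cand, genome) is None

    def test_all_planted_tsds_recovered(self, small_sim, small_scan):
        candidates, _ = small_scan
        tmap = {(t.chrom, t.start, t.end): t.tsd for t in small_sim["truths"]
                if t.type.startswith("packtir")}
        checked = 0
        for c in candidates:
            key = (c.chrom, *c.element_span)
            if c.passed and key in tmap:
                assert c.tsd is not None and c.tsd.seq == tmap[key]
                checked += 1
        assert checked == len(tmap)


class TestFamilies:
    def _mock_candidate(self, cid, chrom, start, internal, parent_span, tsd,
                        rng):
        left = TEAnnotationRecord(chrom, start, start + 50, "+", "TE1")
        right = TEAnnotationRecord(chrom, start + 50 + len(internal),
                                   start + 100 + len(internal), "+", "TE1")
        c = PackTIRCandidate(cid, chrom, left, right,
                             (start + 50, start + 50 + len(internal)),
                             internal, ConsensusTE("TE1", random_dna(rng, 60)))
        from packtir.homology import AlignmentHit
        hit = AlignmentHit((0, len(internal)), "chrP", parent_span, "+",
                           len(internal), 0, 0, 0)
        c.parent = ParentHit(hit, 1000, None, 1.0)
        c.status = "pass"
        c.tsd = TSDCall(tsd, start - len(tsd), start + 100 + len(internal))
        return c

    def test_single_candidate_single_family(self, rng):
        internal = random_dna(rng, 200)
        c = self._mock_candidate("A", "chr1", 1000, internal, (0, 200),
                                 "ACGT", rng)
        (fam,) = group_into_families([c])
        assert fam.copy_number == 1
        assert fam.classification == "single-copy"

    def test_identical_tsds_flagged_ambiguous_not_multicopy(self, rng):
        internal = random_dna(rng, 200)
        a = self._mock_candidate("A", "chr1", 1000, internal, (0, 200),
                                 "ACGT", rng)
        b = self._mock_candidate("B", "chr2", 5000, internal, (0, 200),
                                 "ACGT", rng)
        (fam,) = group_into_families([a, b])
        assert fam.copy_number == 2
        assert fam.classification == "single-copy"
        assert fam.ambiguous_identical_tsds

    def test_distinct_tsds_classified_multicopy(self, rng):
        internal = random_dna(rng, 200)
        a = self._mock_candidate("A", "chr1", 1000, internal, (0, 200),
                                 "ACGT", rng)
        b = self._mock_candidate("B", "chr2", 5000, internal, (0, 200),
                                 "TTAA", rng)
        (fam,) = group_into_families([a, b])
        assert fam.classification == "multicopy"
        assert fam.distinct_tsds == ["ACGT", "TTAA"]

    def test_simulated_multicopy_family_recovered(self, small_sim, small_scan):
        candidates, families = small_scan
        planted = [t for t in small_sim["truths"]
                   if t.type == "packtir_fostest"]
        assert len(planted) == 3
        mc = [f for f in families if f.classification == "multicopy"]
        assert len(mc) == 1
        assert mc[0].copy_number == 3
        assert len(mc[0].distinct_tsds) == 3


class TestScanInvariants:
    def test_recovery_on_small_simulation(self, small_sim, small_scan):
        candidates, _ = small_scan
        truth_loci = {(t.chrom, t.start, t.end) for t in small_sim["truths"]
                      if t.type.startswith("packtir")}
        pass_loci = {(c.chrom, *c.element_span) for c in candidates
                     if c.passed}
        assert truth_loci == pass_loci

    def test_pass_set_satisfies_numeric_bounds(self, small_scan):
        candidates, _ = small_scan
        validate_pass_set(candidates, ScanParams())

    def test_doubling_max_internal_len_is_stable(self, small_sim):
        """With all planted captures < 5 kb, a 10 kb cutoff finds nothing
        new."""
        base = run_scan(small_sim["annotations"], small_sim["genome"],
                        small_sim["library"], small_sim["genes"],
                        ScanParams())[0]
        wide = run_scan(small_sim["annotations"], small_sim["genome"],
                        small_sim["library"], small_sim["genes"],
                        ScanParams(max_internal_len=10_000))[0]
        key = lambda cands: {(c.chrom, *c.element_span)
                             for c in cands if c.passed}
        assert key(base) == key(wide)

    def test_zero_te_annotation_yields_nothing(self, small_sim):
        cands, fams = run_scan([], small_sim["genome"], small_sim["library"])
        assert cands == [] and fams == []
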