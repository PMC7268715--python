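"""offtarget: anchored alignment, classification rules, counting, prefilter.

Oracles used here:

* edlib's global (NW) edit distance for ``total_edits`` of the 19-vs-19
  anchored subproblem;
* a bounded depth-first enumeration of *all* minimum-cost alignment paths
  for ``seed_edits`` (independent of the package's DP);
* naive per-pair scanning (align + classify every candidate in a Python
  loop) for the counting pipeline.
"""

import random

import edlib
import pytest

from cas16s.guides import GuideSite
from cas16s.offtarget import (
    CandidateSite,
    OffTargetCriteria,
    align_guide_candidate,
    classify_offtarget,
    count_offtargets,
    extract_candidate_sites,
    prefilter_candidates,
)
from cas16s.seqio import NucSequence, reverse_complement
from cas16s.simulate import PlantSpec, generate_reference_db

CRIT = OffTargetCriteria()


# ---------------------------------------------------------------------------
# oracle helpers


def dfs_min_total_seed(guide: str, cand: str, seed_len: int = 12) -> tuple[int, int]:
    """Lexicographic (total, seed) minimum by exhaustive bounded path search.

    Explores every alignment path of the 19-vs-19 subproblem whose cost does
    not exceed the edlib optimum, tracking seed-region edits under the same
    assignment convention the package documents (mismatch/deletion -> the
    guide position consumed; insertion -> the adjacent PAM-proximal guide
    position).  Exponential, so callers keep the edit count small.
    """
    g, c = guide[:19], cand[:19]
    opt = edlib.align(g, c, mode="NW", task="distance")["editDistance"]
    in_seed = lambda i: i >= 20 - seed_len  # full-guide index
    best = [opt, 10**9]

    def go(i, j, total, seed):
        if total > opt:
            return
        if total + abs((19 - i) - (19 - j)) > opt:
            return
        if i == 19 and j == 19:
            if total == opt and seed < best[1]:
                best[1] = seed
            return
        if i < 19 and j < 19:
            mm = 0 if g[i] == c[j] else 1
            go(i + 1, j + 1, total + mm, seed + (mm if in_seed(i) else 0))
        if i < 19:  # deletion of guide base i
            go(i + 1, j, total + 1, seed + (1 if in_seed(i) else 0))
        if j < 19:  # insertion adjacent to guide index i
            go(i, j + 1, total + 1, seed + (1 if in_seed(i) else 0))

    go(0, 0, 0, 0)
    return opt, best[1]


def mutate(guide: str, rng: random.Random, n_sub=0, n_del=0, n_ins=0, region=None) -> str:
    """Apply edits to a guide 20-mer, padding/trimming back to 20 nt at the
    PAM-distal end so the PAM-proximal anchor is preserved."""
    s = list(guide)
    positions = region if region is not None else range(1, 20)  # never touch index 19
    idx = rng.sample(list(positions), n_sub + n_del)
    for i in idx[:n_sub]:
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    for i in sorted(idx[n_sub:], reverse=True):
        del s[i]
    for _ in range(n_ins):
        i = rng.randrange(1, len(s) - 1)
        s.insert(i, rng.choice("ACGT"))
    out = "".join(s)
    if len(out) < 20:
        out = "".join(rng.choice("ACGT") for _ in range(20 - len(out))) + out
    return out[-20:]


def naive_count(guides, refs, criteria, exclude=frozenset(), count_sites=False):
    """Independent all-pairs scan: classify every candidate with the scalar API."""
    results = {}
    for g in guides:
        hits_refs = set()
        hit_class = {}
        n_sites = {"NGG": 0, "NAG": 0}
        for ref in refs:
            if ref.id in exclude or ref.id == g.source_id:
                continue
            for site in extract_candidate_sites([ref]):
                aln = align_guide_candidate(g.protospacer, site.protospacer, criteria)
                aln = type(aln)(
                    guide_id=g.guide_id,
                    candidate=site,
                    total_edits=aln.total_edits,
                    seed_edits=aln.seed_edits,
                    anchored_match=aln.anchored_match,
                )
                call = classify_offtarget(aln, criteria)
                if call.is_offtarget:
                    hits_refs.add(ref.id)
                    n_sites[site.pam_class] += 1
                    if hit_class.get(ref.id) != "NGG":
                        hit_class[ref.id] = site.pam_class
        if count_sites:
            results[g.guide_id] = (n_sites["NGG"] + n_sites["NAG"], n_sites["NGG"], n_sites["NAG"])
        else:
            ngg = sum(1 for v in hit_class.values() if v == "NGG")
            results[g.guide_id] = (len(hits_refs), ngg, len(hits_refs) - ngg)
    return results


def _guide(protospacer, gid="g1", source="host"):
    return GuideSite(
        guide_id=gid, source_id=source, strand="+", start=0, end=20, protospacer=protospacer, pam="AGG"
    )


# ---------------------------------------------------------------------------
# candidate extraction


class TestExtractCandidates:
    def test_constructed_ngg_site(self):
        ref = NucSequence(id="r", residues="C" * 20 + "TGG")
        sites = [s for s in extract_candidate_sites([ref]) if s.strand == "+"]
        assert [s.pam_class for s in sites] == ["NGG"]
        assert sites[0].protospacer == "C" * 20

    def test_constructed_nag_site(self):
        ref = NucSequence(id="r", residues="C" * 20 + "TAG")
        sites = [s for s in extract_candidate_sites([ref]) if s.strand == "+"]
        assert [s.pam_class for s in sites] == ["NAG"]

    def test_matches_brute_force_window_scan(self, random_refs):
        from conftest import brute_force_pam_windows

        refs = random_refs(100, 300, seed=2)
        got = sum(1 for _ in extract_candidate_sites(refs))
        expected = sum(
            len(brute_force_pam_windows(r.residues, pam_dinucs=("GG", "AG"))) for r in refs
        )
        assert got == expected

    def test_ambiguous_window_skipped_by_default(self):
        ref = NucSequence(id="r", residues="C" * 10 + "N" + "C" * 9 + "TGG")
        assert list(extract_candidate_sites([ref], both_strands=False)) == []

    def test_strict_mode_counts_ambiguity_as_mismatch(self):
        ref = NucSequence(id="r", residues="C" * 10 + "N" + "C" * 9 + "TGG")
        sites = list(extract_candidate_sites([ref], both_strands=False, ambiguous="mismatch"))
        assert len(sites) == 1
        aln = align_guide_candidate("C" * 20, sites[0].protospacer)
        assert aln.total_edits == 1  # the sentinel can never match


# ---------------------------------------------------------------------------
# anchored alignment


class TestAlignment:
    def test_identity(self):
        aln = align_guide_candidate("ACGT" * 5, "ACGT" * 5)
        assert (aln.total_edits, aln.seed_edits, aln.anchored_match) == (0, 0, True)

    def test_substitution_outside_seed(self):
        guide = "ACGT" * 5
        cand = list(guide)
        cand[20 - 15] = "C" if cand[5] != "C" else "A"  # position 15 from the PAM
        aln = align_guide_candidate(guide, "".join(cand))
        assert (aln.total_edits, aln.seed_edits) == (1, 0)

    def test_substitution_in_seed(self):
        guide = "ACGT" * 5
        cand = list(guide)
        i = 20 - 5  # position 5 from the PAM, inside the 12-nt seed
        cand[i] = "C" if cand[i] != "C" else "A"
        aln = align_guide_candidate(guide, "".join(cand))
        assert (aln.total_edits, aln.seed_edits) == (1, 1)

    def test_pam_adjacent_substitution_breaks_anchor(self):
        guide = "ACGT" * 5
        cand = guide[:19] + ("A" if guide[19] != "A" else "C")
        aln = align_guide_candidate(guide, cand)
        assert not aln.anchored_match
        assert aln.total_edits == 0  # the 19-mer prefix is untouched

    @pytest.mark.parametrize("bad", ["ACGT", "A" * 21, "N" * 20])
    def test_rejects_bad_input(self, bad):
        with pytest.raises(ValueError):
            align_guide_candidate("A" * 20, bad)

    def test_total_edits_match_edlib_on_random_pairs(self, random_dna):
        rng = random.Random(99)
        for trial in range(1000):
            g = random_dna(20, seed=trial)
            if rng.random() < 0.5:
                c = random_dna(20, seed=100_000 + trial)
            else:
                c = mutate(g, rng, n_sub=rng.randint(0, 4), n_del=rng.randint(0, 2), n_ins=rng.randint(0, 2))
            aln = align_guide_candidate(g, c)
            expected = edlib.align(g[:19], c[:19], mode="NW", task="distance")["editDistance"]
            assert aln.total_edits == expected, (g, c)

    def test_seed_edits_match_exhaustive_path_search(self, random_dna):
        rng = random.Random(17)
        checked = 0
        for trial in range(400):
            g = random_dna(20, seed=5000 + trial)
            c = mutate(
                g, rng, n_sub=rng.randint(0, 3), n_del=rng.randint(0, 1), n_ins=rng.randint(0, 1)
            )
            opt, seed_opt = dfs_min_total_seed(g, c)
            if opt > 6:
                continue  # keep the exhaustive oracle tractable
            aln = align_guide_candidate(g, c)
            assert (aln.total_edits, aln.seed_edits) == (opt, seed_opt), (g, c)
            checked += 1
        assert checked > 300

    def test_seed_edits_minimized_over_cooptimal_alignments(self):
        # a deletion can be placed on either side of a repeat; the aligner
        # must choose the placement that empties the seed when possible
        guide = "AAAACCCCGGGGTTTTACGT"
        # delete a base in the PAM-distal half of a run that extends into the seed
        cand = "A" + guide[:19]  # shift right by one: one edit, placeable outside seed
        aln = align_guide_candidate(guide, cand)
        assert aln.total_edits <= 2
        opt, seed_opt = dfs_min_total_seed(guide, cand)
        assert (aln.total_edits, aln.seed_edits) == (opt, seed_opt)


# ---------------------------------------------------------------------------
# classification


def _aln(total, seed, anchored, pam_class):
    site = CandidateSite(
        ref_id="r", strand="+", start=0, end=20, protospacer="A" * 20, pam_class=pam_class
    )
    from cas16s.offtarget import GuideCandidateAlignment

    return GuideCandidateAlignment(
        guide_id="g", candidate=site, total_edits=total, seed_edits=seed, anchored_match=anchored
    )


class TestClassification:
    # the eight canonical cases: exact match; <4 NGG; =4 outside seed NGG;
    # =4 one-in-seed NGG; <2 NAG; =2 outside seed NAG; =2 one-in-seed NAG;
    # anchored failure
    @pytest.mark.parametrize(
        "total,seed,anchored,pam,expected,rule",
        [
            (0, 0, True, "NGG", True, "below_threshold"),
            (3, 3, True, "NGG", True, "below_threshold"),
            (4, 0, True, "NGG", True, "at_threshold_outside_seed"),
            (4, 1, True, "NGG", False, "rejected"),
            (1, 0, True, "NAG", True, "below_threshold"),
            (2, 0, True, "NAG", True, "at_threshold_outside_seed"),
            (2, 1, True, "NAG", False, "rejected"),
            (0, 0, False, "NGG", False, "anchored_fail"),
        ],
    )
    def test_canonical_cases(self, total, seed, anchored, pam, expected, rule):
        call = classify_offtarget(_aln(total, seed, anchored, pam), CRIT)
        assert call.is_offtarget is expected
        assert call.rule_fired == rule

    def test_five_edits_never_qualify(self):
        call = classify_offtarget(_aln(5, 0, True, "NGG"), CRIT)
        assert not call.is_offtarget

    def test_pure_function(self):
        a = _aln(3, 1, True, "NGG")
        assert classify_offtarget(a, CRIT) == classify_offtarget(a, CRIT)


# ---------------------------------------------------------------------------
# prefilter


class TestPrefilter:
    def test_identical_site_passes(self):
        g = "ACGTACGTACGTACGTACGT"
        site = CandidateSite(ref_id="r", strand="+", start=0, end=20, protospacer=g, pam_class="NGG")
        assert list(prefilter_candidates(g, [site], CRIT)) == [site]

    def test_unrelated_site_dropped_and_is_not_an_offtarget(self):
        g = "A" * 20
        c = "C" * 10 + "G" * 10  # zero shared 4-mers, >8 mismatches
        site = CandidateSite(ref_id="r", strand="+", start=0, end=20, protospacer=c, pam_class="NGG")
        assert list(prefilter_candidates(g, [site], CRIT)) == []
        # dropping it is lossless: exhaustive classification rejects it anyway
        aln = align_guide_candidate(g, c, CRIT)
        call = classify_offtarget(_aln(aln.total_edits, aln.seed_edits, aln.anchored_match, "NGG"), CRIT)
        assert not call.is_offtarget

    def test_planted_low_edit_sites_always_pass(self, random_dna):
        rng = random.Random(23)
        for trial in range(300):
            g = random_dna(20, seed=30_000 + trial)
            c = mutate(g, rng, n_sub=rng.randint(0, 4))
            site = CandidateSite(
                ref_id="r", strand="+", start=0, end=20, protospacer=c, pam_class="NGG"
            )
            assert list(prefilter_candidates(g, [site], CRIT)) == [site]


# ---------------------------------------------------------------------------
# counting pipeline


class TestCountOfftargets:
    def test_empty_reference_all_zero(self):
        g = _guide("ACGT" * 5)
        reports = count_offtargets([g], [], CRIT)
        assert reports[0].n_offtargets == 0
        assert reports[0].passes_cutoff

    def test_planted_sites_counted_per_sequence(self, random_dna):
        guide = random_dna(20, seed=77)
        k = 7
        plants = [PlantSpec(guide=guide, n_edits=2, edit_positions=frozenset({5, 15})) for _ in range(k)]
        refs, _ = generate_reference_db(50, 120, plants, seed=4)
        reports = count_offtargets([_guide(guide)], refs, CRIT)
        assert reports[0].n_offtargets == k
        naive = naive_count([_guide(guide)], refs, CRIT)
        assert (
            reports[0].n_offtargets,
            reports[0].n_offtargets_ngg,
            reports[0].n_offtargets_nag,
        ) == naive["g1"]

    def test_count_sites_mode(self, random_dna):
        guide = random_dna(20, seed=78)
        plants = [PlantSpec(guide=guide, n_edits=0) for _ in range(3)]
        refs, _ = generate_reference_db(2, 200, plants, seed=9)  # 3 plants on 2 seqs
        seq_reports = count_offtargets([_guide(guide)], refs, CRIT)
        site_reports = count_offtargets([_guide(guide)], refs, CRIT, count_sites=True)
        assert seq_reports[0].n_offtargets == 2
        assert site_reports[0].n_offtargets >= 3

    def test_exclusion_and_self_hit_skipped(self, random_dna):
        guide = random_dna(20, seed=80)
        plants = [PlantSpec(guide=guide, n_edits=0) for _ in range(2)]
        refs, planted = generate_reference_db(2, 100, plants, seed=12)
        g = _guide(guide, source="synth_0")  # self-hit: synth_0 must be skipped
        reports = count_offtargets([g], refs, CRIT)
        assert reports[0].n_offtargets == 1
        reports2 = count_offtargets([g], refs, CRIT, exclude_ref_ids={"synth_1"})
        assert reports2[0].n_offtargets == 0

    def test_ranking_monotone_and_deterministic(self, random_dna):
        g_bad = random_dna(20, seed=81)
        g_clean = random_dna(20, seed=82)
        plants = [PlantSpec(guide=g_bad, n_edits=1, edit_positions=frozenset({15})) for _ in range(5)]
        refs, _ = generate_reference_db(30, 120, plants, seed=6)
        reports = count_offtargets([_guide(g_bad, "bad"), _guide(g_clean, "clean")], refs, CRIT)
        assert [r.guide_id for r in reports] == ["clean", "bad"]
        assert [r.rank for r in reports] == [1, 2]
        assert reports[1].n_offtargets >= 5

    def test_prefilter_neutral_on_random_instances(self, random_refs, random_dna):
        rng = random.Random(1)
        for inst in range(3):
            refs = random_refs(40, 150, seed=200 + inst)
            guides = []
            for gi in range(6):
                base = random_dna(20, seed=900 + 10 * inst + gi)
                guides.append(_guide(base, gid=f"g{gi}"))
            with_f = count_offtargets(guides, refs, CRIT, prefilter=True)
            without = count_offtargets(guides, refs, CRIT, prefilter=False)
            assert with_f == without

    def test_matches_naive_all_pairs_scan(self, random_refs, random_dna):
        refs = random_refs(15, 120, seed=33)
        rng = random.Random(5)
        # guides derived from reference content so some hits exist
        guides = []
        for gi in range(4):
            src = refs[gi].residues
            window = src[10:30]
            guides.append(_guide(mutate(window, rng, n_sub=rng.randint(0, 2)), gid=f"g{gi}"))
        reports = count_offtargets(guides, refs, CRIT)
        naive = naive_count(guides, refs, CRIT)
        for r in reports:
            assert (r.n_offtargets, r.n_offtargets_ngg, r.n_offtargets_nag) == naive[r.guide_id]

    def test_strand_invariance(self, random_dna):
        guide = random_dna(20, seed=85)
        plants = [PlantSpec(guide=guide, n_edits=1, edit_positions=frozenset({18}))]
        refs, _ = generate_reference_db(20, 150, plants, seed=8)
        flipped = [NucSequence(id=r.id, residues=reverse_complement(r.residues)) for r in refs]
        a = count_offtargets([_guide(guide)], refs, CRIT)
        b = count_offtargets([_guide(guide)], flipped, CRIT)
        assert a == b

    def test_monotonicity_in_criteria(self, random_refs, random_dna):
        refs = random_refs(25, 140, seed=44)
        rng = random.Random(9)
        guides = [
            _guide(mutate(refs[i].residues[20:40], rng, n_sub=2), gid=f"g{i}") for i in range(4)
        ]
        base = {r.guide_id: r.n_offtargets for r in count_offtargets(guides, refs, CRIT)}
        looser = OffTargetCriteria(max_edits_ngg=5, max_edits_nag=3)
        more = {r.guide_id: r.n_offtargets for r in count_offtargets(guides, refs, looser)}
        shorter_seed = OffTargetCriteria(seed_len=6)
        rescue = {r.guide_id: r.n_offtargets for r in count_offtargets(guides, refs, shorter_seed)}
        for gid in base:
            assert more[gid] >= base[gid]
            assert rescue[gid] >= base[gid]

    def test_cutoff_fraction(self, random_refs):
        refs = random_refs(10, 100, seed=55)
        g = _guide("ACGT" * 5)
        reports = count_offtargets([g], refs, CRIT, cutoff_fraction=0.001)
        # 0.1% of 10 references rounds down to 0 -> nothing can pass
        assert not reports[0].passes_cutoff
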