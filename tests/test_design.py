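"""Boundary-anchored walker: enumeration, ranking, pair assembly, batches."""

from dataclasses import replace

import pytest
from hypothesis import given
from hypothesis import strategies as st

from primerwalk import (
    AlphabetError,
    BufferConditions,
    DesignFailure,
    DesignSpec,
    DuplicateIdError,
    NoCandidateError,
    PrimerCandidate,
    TemplateTooShortError,
    design_batch,
    design_pair,
    enumerate_candidates,
    melting_temperature,
    rank_and_pick,
    reverse_complement,
)

from conftest import random_seq

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


@pytest.fixture
def spec():
    return DesignSpec(tm_optimal=60.0, tm_tolerance=5.0)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ACGT"), ("AAAA", "TTTT"), ("GATTACA", "TGTAATC"), ("G", "C")],
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_rejects_bad_alphabet(self):
        with pytest.raises(AlphabetError):
            reverse_complement("ACGN")


def brute_force_enumerate(template, orientation, spec, params, buffer):
    """Independent all-lengths enumeration + window filter."""
    out = []
    for length in range(spec.min_len, min(spec.max_len, len(template)) + 1):
        seq = (
            template[:length]
            if orientation == "forward"
            else reverse_complement(template[-length:])
        )
        tm = melting_temperature(seq, params, buffer).tm_celsius
        if abs(tm - spec.tm_optimal) <= spec.tm_tolerance:
            out.append((seq, length, tm, seq[-1] in "GC"))
    return out


class TestEnumerateCandidates:
    def test_template_too_short(self, spec, santalucia, buffer_default):
        with pytest.raises(TemplateTooShortError):
            enumerate_candidates("A" * (spec.min_len - 1), "forward", spec, santalucia, buffer_default)

    def test_poly_a_cannot_reach_hot_window(self, santalucia, buffer_default):
        hot = DesignSpec(tm_optimal=95.0, tm_tolerance=1.0)
        cands = enumerate_candidates("A" * 200, "forward", hot, santalucia, buffer_default)
        assert cands == []
        # confirm the premise: every poly-A candidate melts far below 94 degC
        for L in range(hot.min_len, hot.max_len + 1):
            tm = melting_temperature("A" * L, santalucia, buffer_default).tm_celsius
            assert tm < 94.0

    @pytest.mark.parametrize("orientation", ["forward", "reverse"])
    def test_matches_brute_force_oracle(self, spec, santalucia, buffer_default, rng, orientation):
        for _ in range(100):
            template = random_seq(rng, int(rng.integers(40, 501)))
            got = enumerate_candidates(template, orientation, spec, santalucia, buffer_default)
            want = brute_force_enumerate(template, orientation, spec, santalucia, buffer_default)
            assert [(c.annealing_seq, c.length, c.tm, c.ends_gc) for c in got] == want

    def test_ordered_by_increasing_length(self, spec, santalucia, buffer_default, rng):
        template = random_seq(rng, 300)
        cands = enumerate_candidates(template, "forward", spec, santalucia, buffer_default)
        assert [c.length for c in cands] == sorted(c.length for c in cands)

    def test_anchoring(self, spec, santalucia, buffer_default, rng):
        template = random_seq(rng, 300)
        for c in enumerate_candidates(template, "forward", spec, santalucia, buffer_default):
            assert template.startswith(c.annealing_seq)
        for c in enumerate_candidates(template, "reverse", spec, santalucia, buffer_default):
            assert template.endswith(reverse_complement(c.annealing_seq))


def _cand(tm, length, ends_gc):
    seq = ("A" * (length - 1)) + ("G" if ends_gc else "A")
    return PrimerCandidate(seq, length, tm, ends_gc, "forward")


def brute_force_pick(candidates, spec):
    """Exhaustive scoring by the documented lexicographic key."""
    pool = candidates
    if spec.force_gc_clamp and any(c.ends_gc for c in candidates):
        pool = [c for c in candidates if c.ends_gc]
    best = None
    for c in pool:
        key = (abs(c.tm - spec.tm_optimal), c.length, 0 if c.ends_gc else 1)
        if best is None or key < best[0]:
            best = (key, c)
    return best[1]


class TestRankAndPick:
    def test_single_candidate_no_warning(self, spec):
        c = _cand(60.3, 20, False)
        picked, warnings = rank_and_pick([c], replace(spec, force_gc_clamp=False))
        assert picked is c and warnings == []

    def test_clamp_dominates_closeness(self, spec):
        near_a = _cand(60.3, 20, False)
        far_g = _cand(60.9, 22, True)
        picked, warnings = rank_and_pick([near_a, far_g], spec)
        assert picked is far_g and warnings == []

    def test_clamp_off_picks_global_best(self, spec):
        near_a = _cand(60.3, 20, False)
        far_g = _cand(60.9, 22, True)
        picked, _ = rank_and_pick([near_a, far_g], replace(spec, force_gc_clamp=False))
        assert picked is near_a

    def test_clamp_unavailable_warns(self, spec):
        a1, a2 = _cand(61.0, 20, False), _cand(60.2, 25, False)
        picked, warnings = rank_and_pick([a1, a2], spec)
        assert picked is a2
        assert any("clamp" in w for w in warnings)

    def test_tie_breaks_to_shorter_then_clamp(self, spec):
        no_clamp = replace(spec, force_gc_clamp=False)
        longer, shorter = _cand(61.0, 24, False), _cand(61.0, 20, False)
        assert rank_and_pick([longer, shorter], no_clamp)[0] is shorter
        plain, clamped = _cand(61.0, 20, False), _cand(61.0, 20, True)
        assert rank_and_pick([plain, clamped], no_clamp)[0] is clamped

    def test_empty_raises(self, spec):
        with pytest.raises(NoCandidateError):
            rank_and_pick([], spec)

    @pytest.mark.parametrize("force_clamp", [True, False])
    def test_matches_brute_force_comparator(self, rng, force_clamp):
        spec = DesignSpec(tm_optimal=60.0, tm_tolerance=5.0, force_gc_clamp=force_clamp)
        for _ in range(50):
            n = int(rng.integers(1, 12))
            cands = [
                _cand(
                    round(float(rng.uniform(55, 65)), 1),
                    int(rng.integers(15, 41)),
                    bool(rng.integers(0, 2)),
                )
                for _ in range(n)
            ]
            picked, _ = rank_and_pick(cands, spec)
            assert picked == brute_force_pick(cands, spec)

    def test_clamp_soundness_randomized(self, rng):
        """With the clamp forced, the pick ends G/C whenever any candidate does."""
        spec = DesignSpec(force_gc_clamp=True)
        for _ in range(200):
            n = int(rng.integers(1, 10))
            cands = [
                _cand(float(rng.uniform(55, 65)), int(rng.integers(15, 41)), bool(rng.integers(0, 2)))
                for _ in range(n)
            ]
            picked, _ = rank_and_pick(cands, spec)
            if any(c.ends_gc for c in cands):
                assert picked.ends_gc


class TestDesignPair:
    def test_precision_invariant(self, santalucia, buffer_default, rng):
        """Stripping extensions recovers an exact prefix / rc'd suffix."""
        spec = DesignSpec(ext_forward="GGTCTCA", ext_reverse="TTGAAGAC")
        for _ in range(25):
            template = random_seq(rng, int(rng.integers(100, 400)))
            pair = design_pair(("t", template), spec, santalucia, buffer_default)
            fwd = pair.forward_full[len(spec.ext_forward):]
            rev = pair.reverse_full[len(spec.ext_reverse):]
            assert template.startswith(fwd)
            assert template.endswith(reverse_complement(rev))

    def test_empty_extensions(self, santalucia, buffer_default, rng):
        template = random_seq(rng, 200)
        pair = design_pair(("t", template), DesignSpec(), santalucia, buffer_default)
        assert pair.forward_full == pair.forward_candidate.annealing_seq
        assert pair.reverse_full == pair.reverse_candidate.annealing_seq

    def test_window_soundness_recomputed(self, santalucia, buffer_default, rng):
        spec = DesignSpec()
        for _ in range(10):
            template = random_seq(rng, 300)
            pair = design_pair(("t", template), spec, santalucia, buffer_default)
            for cand in (pair.forward_candidate, pair.reverse_candidate):
                tm = melting_temperature(cand.annealing_seq, santalucia, buffer_default).tm_celsius
                assert abs(tm - spec.tm_optimal) <= spec.tm_tolerance

    def test_unreachable_window_fails_with_nearest_tm(self, santalucia, buffer_default):
        hot = DesignSpec(tm_optimal=95.0, tm_tolerance=1.0)
        with pytest.raises(DesignFailure) as exc:
            design_pair(("t", "AT" * 100), hot, santalucia, buffer_default)
        assert exc.value.nearest_tm is not None
        assert "nearest achievable" in exc.value.reason

    def test_auto_widen_recovers_hard_record(self, santalucia, buffer_default):
        hard = DesignSpec(tm_optimal=60.0, tm_tolerance=1.0)
        template = "AT" * 60 + "GC" * 40
        with pytest.raises(DesignFailure):
            design_pair(("t", template), hard, santalucia, buffer_default)
        pair = design_pair(("t", template), hard, santalucia, buffer_default, auto_widen=2.0)
        assert any("widened" in w for w in pair.warnings)


class TestDesignBatch:
    def test_all_designable(self, santalucia, buffer_default, rng):
        records = [(f"r{i}", random_seq(rng, 250)) for i in range(10)]
        pairs, failures = design_batch(records, DesignSpec(), santalucia, buffer_default)
        assert len(pairs) == 10 and failures == []
        assert [p.record_id for p in pairs] == [r[0] for r in records]

    def test_short_record_collected_not_raised(self, santalucia, buffer_default, rng):
        records = [("ok1", random_seq(rng, 250)), ("tiny", "ACGTACGTAC"), ("ok2", random_seq(rng, 250))]
        pairs, failures = design_batch(records, DesignSpec(), santalucia, buffer_default)
        assert [p.record_id for p in pairs] == ["ok1", "ok2"]
        assert [f.record_id for f in failures] == ["tiny"]

    def test_duplicate_ids_rejected_upfront(self, santalucia, buffer_default, rng):
        records = [("a", random_seq(rng, 250)), ("a", random_seq(rng, 250))]
        with pytest.raises(DuplicateIdError):
            design_batch(records, DesignSpec(), santalucia, buffer_default)

    def test_permutation_invariance(self, santalucia, buffer_default, rng):
        records = [(f"r{i}", random_seq(rng, 250)) for i in range(8)]
        pairs1, _ = design_batch(records, DesignSpec(), santalucia, buffer_default)
        shuffled = list(records)
        rng.shuffle(shuffled)
        pairs2, _ = design_batch(shuffled, DesignSpec(), santalucia, buffer_default)
        by_id = {p.record_id: p for p in pairs2}
        assert all(by_id[p.record_id] == p for p in pairs1)

    def test_determinism(self, santalucia, buffer_default, rng):
        records = [(f"r{i}", random_seq(rng, 250)) for i in range(5)]
        run1, _ = design_batch(records, DesignSpec(), santalucia, buffer_default)
        run2, _ = design_batch(records, DesignSpec(), santalucia, buffer_default)
        assert run1 == run2


class TestDesignSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tm_tolerance": 0.0},
            {"min_len": 1},
            {"min_len": 30, "max_len": 20},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DesignSpec(**kwargs)

    def test_bad_extension_rejected(self):
        with pytest.raises(AlphabetError):
            DesignSpec(ext_forward="GGTCTN")
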