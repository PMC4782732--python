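"""Sliding-window similarity score against brute-force window oracles."""

import numpy as np
import pytest

from san1score import (
    Run,
    ScoreParams,
    initial_score,
    san1_similarity,
    score_profile,
    valid_centers,
    window_components,
)
from conftest import make_annotated, random_annotated


def brute_window(protein, params, center):
    """Pure-Python recomputation of the three window quantities."""
    w = params.window
    half = w // 2
    s, e = center - half, center + half
    disorder = sum(
        1 for v in protein.disorder.values[s:e] if v > params.disorder_threshold
    ) / w

    # global qualification: maximal anchor runs on the full protein
    bits = "".join(
        "1" if v > params.anchor_threshold else "0" for v in protein.anchor.values
    )
    covered = set()
    pos = 0
    for chunk in bits.split("0"):
        if params.stretch_min <= len(chunk) <= params.stretch_max:
            covered.update(range(pos, pos + len(chunk)))
        pos += len(chunk) + 1
    anchor = sum(1 for i in range(s, e) if i in covered) / w

    kfree = max(len(seg) for seg in protein.record.sequence[s:e].split("K")) / w
    return disorder, anchor, kfree


class TestWindowComponents:
    def test_periodic_anchor_pattern(self):
        # fully disordered, lysine-free window; anchor plateau pattern of
        # 20 positive / 10 negative with period 30 dividing 150, so any
        # window phase covers exactly 100 stretch residues
        n = 300
        anchor = np.tile(np.r_[np.full(20, 0.9), np.full(10, 0.1)], n // 30)
        p = make_annotated("p", "A" * n, np.full(n, 0.9), anchor)
        for center in (75, 100, 151):
            c = window_components(p, ScoreParams(), center)
            assert c.disorder_frac == 1.0
            assert c.anchor_stretch_frac == pytest.approx(100 / 150)
            assert c.kfree_frac == 1.0
            assert c.product == pytest.approx(2 / 3, abs=1e-4)

    def test_zero_tracks_no_lysines(self):
        p = make_annotated("p", "A" * 200, np.zeros(200), np.zeros(200))
        c = window_components(p, ScoreParams(), 100)
        assert (c.disorder_frac, c.anchor_stretch_frac, c.kfree_frac) == (0, 0, 1.0)
        assert c.product == 0.0

    def test_all_lysine_window(self):
        p = make_annotated("p", "K" * 200, np.full(200, 0.9), np.zeros(200))
        c = window_components(p, ScoreParams(), 100)
        assert c.kfree_frac == 0.0 and c.product == 0.0

    def test_center_outside_range_is_an_error(self):
        p = make_annotated("p", "A" * 200, np.zeros(200), np.zeros(200))
        for bad in (74, 125, 300):
            with pytest.raises(ValueError, match="outside defined range"):
                window_components(p, ScoreParams(), bad)

    def test_matches_pure_python_oracle(self, rng):
        for _ in range(10):
            p = random_annotated(rng, int(rng.integers(160, 400)))
            params = ScoreParams()
            centers = valid_centers(len(p), params)
            for center in rng.integers(centers.start, centers.end, size=5):
                c = window_components(p, params, int(center))
                d, a, k = brute_window(p, params, int(center))
                assert (c.disorder_frac, c.anchor_stretch_frac, c.kfree_frac) == (d, a, k)


class TestProfileAndSimilarity:
    def test_profile_equals_per_center_recomputation(self, rng):
        for _ in range(5):
            p = random_annotated(rng, int(rng.integers(151, 400)))
            params = ScoreParams()
            prof = score_profile(p, params)
            for j, center in enumerate(prof.centers):
                c = window_components(p, params, int(center))
                assert prof.disorder_frac[j] == c.disorder_frac
                assert prof.anchor_stretch_frac[j] == c.anchor_stretch_frac
                assert prof.kfree_frac[j] == c.kfree_frac
                assert prof.product[j] == c.product

    def test_short_protein_scores_zero(self, rng):
        p = random_annotated(rng, 149)
        r = san1_similarity(p, ScoreParams())
        assert r.score == 0.0 and r.best is None
        assert r.defined_range.length == 0

    def test_window_sized_protein_has_no_valid_center(self, rng):
        # the score is undefined at the first and last 75 positions, so a
        # 150-residue protein has no defined center and scores zero
        p = random_annotated(rng, 150)
        r = san1_similarity(p, ScoreParams())
        assert r.score == 0.0 and r.best is None

    def test_one_residue_above_window_has_one_center(self, rng):
        p = random_annotated(rng, 151)
        r = san1_similarity(p, ScoreParams())
        assert r.best is not None and r.best.center == 75
        assert r.score == window_components(p, ScoreParams(), 75).product

    def test_max_and_argmax_match_exhaustive_enumeration(self, rng):
        params = ScoreParams()
        for _ in range(15):
            p = random_annotated(rng, int(rng.integers(151, 401)))
            r = san1_similarity(p, params)
            products = {
                c: window_components(p, params, c).product
                for c in range(r.defined_range.start, r.defined_range.end)
            }
            best_score = max(products.values())
            best_center = min(c for c, v in products.items() if v == best_score)
            assert r.score == best_score
            assert r.best.center == best_center

    def test_tie_broken_leftmost(self):
        # symmetric protein: every window product identical -> center 75
        n = 400
        p = make_annotated("p", "A" * n, np.full(n, 0.9), np.zeros(n))
        r = san1_similarity(p, ScoreParams())
        assert r.best.center == 75

    def test_bitwise_determinism(self, rng):
        p = random_annotated(rng, 333)
        r1 = san1_similarity(p, ScoreParams())
        r2 = san1_similarity(p, ScoreParams())
        assert r1 == r2

    def test_components_bounded(self, rng):
        p = random_annotated(rng, 350)
        prof = score_profile(p, ScoreParams())
        for arr in (prof.disorder_frac, prof.anchor_stretch_frac,
                    prof.kfree_frac, prof.product):
            assert np.all((arr >= 0.0) & (arr <= 1.0))


class TestMonotonicity:
    def test_adding_lysine_never_increases_score(self, rng):
        params = ScoreParams()
        for _ in range(20):
            p = random_annotated(rng, int(rng.integers(180, 350)))
            r = san1_similarity(p, params)
            w = r.best.window
            non_k = [i for i in range(w.start, w.end)
                     if p.record.sequence[i] != "K"]
            if not non_k:
                continue
            i = int(rng.choice(non_k))
            seq = p.record.sequence[:i] + "K" + p.record.sequence[i + 1:]
            mutated = make_annotated("p", seq, p.disorder.values, p.anchor.values)
            assert san1_similarity(mutated, params).score <= r.score

    def test_raising_disorder_never_decreases_score(self, rng):
        params = ScoreParams()
        for _ in range(20):
            p = random_annotated(rng, int(rng.integers(180, 350)))
            r = san1_similarity(p, params)
            values = p.disorder.values.copy()
            i = int(rng.integers(0, len(p)))
            values[i] = min(1.0, values[i] + rng.random() * (1 - values[i]))
            raised = make_annotated("p", p.record.sequence, values, p.anchor.values)
            assert san1_similarity(raised, params).score >= r.score


class TestInitialScore:
    def test_product_arithmetic(self):
        n = 100
        disorder = np.r_[np.full(78, 0.9), np.full(22, 0.1)]
        anchor = np.zeros(n)
        anchor[5:25] = 0.9   # one qualifying 20-residue stretch
        anchor[40:60] = 0.9  # and another
        p = make_annotated("p", "A" * n, disorder, anchor)
        s = initial_score(p, ScoreParams())
        assert s.disorder_frac == pytest.approx(0.78)
        assert s.anchor_stretch == pytest.approx(0.40)
        assert s.product == pytest.approx(0.312)

    def test_no_qualifying_stretch_zeroes_product(self):
        p = make_annotated("p", "A" * 100, np.full(100, 0.9), np.full(100, 0.9))
        assert initial_score(p, ScoreParams()).product == 0.0

    def test_product_bounded_by_factors(self, rng):
        for _ in range(30):
            p = random_annotated(rng, int(rng.integers(50, 300)))
            s = initial_score(p, ScoreParams())
            assert s.product <= min(s.disorder_frac, s.anchor_stretch) + 1e-15
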