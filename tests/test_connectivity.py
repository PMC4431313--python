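"""KS enrichment, instance scoring, batch scaling and permutation p-values."""

import random

import numpy as np
import pytest

from netpharm import (
    RankedProfile,
    TagSignature,
    instance_score,
    ks_enrichment,
    mean_scores_with_pvalues,
    scale_scores,
    score_batch,
)


def profile(order, iid="i", pert="p", cell="c"):
    return RankedProfile(iid, pert, cell, tuple(order))


def random_profile(rng, n, iid="i", pert="p", cell="c"):
    tags = ["g%02d" % i for i in range(n)]
    rng.shuffle(tags)
    return profile(tags, iid, pert, cell)


def ks_oracle(tags, prof):
    """Plain-Python argmax over every j — the exhaustive evaluation."""
    t, n = len(tags), prof.n
    v = sorted(prof.rank_of(x) for x in tags)
    a = max(j / t - v[j - 1] / n for j in range(1, t + 1))
    b = max(v[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


class TestKsEnrichment:
    def test_tags_at_top_worked_example(self):
        p = profile("abcdefghij")
        # t=2, n=10, tag ranks {1,2}: a = max(1/2-1/10, 1-2/10) = 0.8
        assert ks_enrichment(("a", "b"), p) == pytest.approx(0.8)

    def test_tags_at_bottom(self):
        p = profile("abcdefghij")
        # ranks {9,10}: b = max(9/10-0, 1-1/2) = 0.9, so score -0.9
        assert ks_enrichment(("i", "j"), p) == pytest.approx(-0.9)

    def test_saturated_signature_is_near_zero(self):
        p = profile("abcdefghij")
        s = ks_enrichment(tuple("abcdefghij"), p)
        assert abs(s) <= 1 / p.n + 1e-12

    def test_absent_tag_raises_naming_it(self):
        p = profile("abc")
        with pytest.raises(KeyError, match="zz"):
            ks_enrichment(("zz",), p)

    def test_agrees_with_exhaustive_oracle(self):
        rng = random.Random(13)
        for _ in range(200):
            n = rng.randint(3, 40)
            prof = random_profile(rng, n)
            t = rng.randint(1, n)
            tags = rng.sample(list(prof.order), t)
            assert ks_enrichment(tags, prof) == pytest.approx(
                ks_oracle(tags, prof), abs=1e-12
            )

    def test_bounded_in_unit_interval(self):
        rng = random.Random(21)
        for _ in range(50):
            prof = random_profile(rng, 20)
            tags = rng.sample(list(prof.order), rng.randint(1, 20))
            assert -1.0 <= ks_enrichment(tags, prof) <= 1.0


class TestInstanceScore:
    def test_coherent_signature_scores_positive(self):
        p = profile("abcdefghij")
        sig = TagSignature(up=("a", "b"), down=("i", "j"))
        assert instance_score(sig, p) > 0

    def test_same_sign_enrichment_scores_zero(self):
        # up and down tags both crowd the top half
        p = profile("abcdefghij")
        sig = TagSignature(up=("a", "b"), down=("c", "d"))
        assert instance_score(sig, p) == 0.0

    def test_swapping_up_and_down_negates_exactly(self):
        rng = random.Random(3)
        for _ in range(100):
            prof = random_profile(rng, 24)
            tags = rng.sample(list(prof.order), 10)
            sig = TagSignature(up=tuple(tags[:5]), down=tuple(tags[5:]))
            swapped = TagSignature(up=sig.down, down=sig.up)
            assert instance_score(swapped, prof) == -instance_score(sig, prof)

    def test_reversing_ranking_negates_up_to_discretization(self):
        # rank reversal maps the KS pair (a, b) to (b - 1/n, a + 1/n), so
        # the raw score flips sign only up to O(1/n)
        rng = random.Random(5)
        n = 40
        for _ in range(100):
            prof = random_profile(rng, n)
            tags = rng.sample(list(prof.order), 12)
            sig = TagSignature(up=tuple(tags[:6]), down=tuple(tags[6:]))
            fwd = instance_score(sig, prof)
            rev = instance_score(sig, prof.reversed())
            if abs(fwd) > 2 / n and abs(rev) > 2 / n:
                assert rev == pytest.approx(-fwd, abs=2 / n)

    def test_up_only_signature_supported(self):
        p = profile("abcdefghij")
        assert instance_score(TagSignature(up=("a", "b")), p) == pytest.approx(0.8)
        assert instance_score(TagSignature(down=("a", "b")), p) == pytest.approx(-0.8)

    def test_signature_validation(self):
        with pytest.raises(ValueError):
            TagSignature()
        with pytest.raises(ValueError):
            TagSignature(up=("a",), down=("a",))


class TestScaling:
    def test_scaled_batch_hits_unit_magnitude(self):
        scaled = scale_scores([0.2, -0.5, 0.1])
        assert np.max(np.abs(scaled)) == pytest.approx(1.0)
        assert scaled[1] == pytest.approx(-1.0)

    def test_empty_batch_is_an_error(self):
        with pytest.raises(ValueError, match="empty batch"):
            scale_scores([])

    def test_all_zero_batch_stays_zero(self):
        assert np.allclose(scale_scores([0.0, 0.0]), 0.0)

    def test_score_batch_bounds_and_extreme(self):
        rng = random.Random(8)
        tags = ["g%02d" % i for i in range(30)]
        profs = []
        for i in range(10):
            order = tags[:]
            rng.shuffle(order)
            profs.append(profile(order, iid="i%d" % i))
        sig = TagSignature(up=tuple(tags[:5]), down=tuple(tags[5:10]))
        scaled = score_batch(sig, profs)
        assert np.all(np.abs(scaled) <= 1.0 + 1e-12)
        raws = [instance_score(sig, p) for p in profs]
        if any(r != 0 for r in raws):
            assert np.max(np.abs(scaled)) == pytest.approx(1.0)


class TestMeanScoresWithPvalues:
    def _self_match_batch(self):
        tags = ["g%02d" % i for i in range(20)]
        sig = TagSignature(up=tuple(tags[:3]), down=tuple(tags[-3:]))
        # instance built from the signature itself: up first, down last
        match = profile(tags, iid="m0", pert="match", cell="X")
        rng = random.Random(2)
        nulls = []
        for i in range(6):
            order = tags[:]
            rng.shuffle(order)
            nulls.append(profile(order, iid="n%d" % i, pert="null%d" % i, cell="X"))
        return sig, [match] + nulls

    def test_self_match_saturates_scale_with_smallest_p(self):
        sig, profs = self._self_match_batch()
        results = mean_scores_with_pvalues(sig, profs, n_perm=99, seed=0)
        top = results[0]
        assert top.perturbagen == "match"
        assert top.mean_score == pytest.approx(1.0)
        assert top.p_value == min(r.p_value for r in results)

    def test_same_seed_reproduces_p_values(self):
        sig, profs = self._self_match_batch()
        r1 = mean_scores_with_pvalues(sig, profs, n_perm=50, seed=5)
        r2 = mean_scores_with_pvalues(sig, profs, n_perm=50, seed=5)
        assert [(r.perturbagen, r.p_value) for r in r1] == [
            (r.perturbagen, r.p_value) for r in r2
        ]

    def test_pvalues_in_half_open_unit_interval(self):
        sig, profs = self._self_match_batch()
        for r in mean_scores_with_pvalues(sig, profs, n_perm=30, seed=1):
            assert 0.0 < r.p_value <= 1.0

    def test_invalid_n_perm_rejected(self):
        sig, profs = self._self_match_batch()
        with pytest.raises(ValueError):
            mean_scores_with_pvalues(sig, profs, n_perm=0, seed=1)

    def test_vectorized_engine_matches_scalar_path(self):
        sig, profs = self._self_match_batch()
        results = mean_scores_with_pvalues(sig, profs, n_perm=1, seed=0)
        scaled = score_batch(sig, profs)
        by_combo = {}
        for p, s in zip(profs, scaled):
            by_combo.setdefault((p.perturbagen, p.cell_line), []).append(s)
        for r in results:
            want = float(np.mean(by_combo[(r.perturbagen, r.cell_line)]))
            assert r.mean_score == pytest.approx(want, abs=1e-12)
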