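"""Rank-based connectivity scoring of an up/down tag signature against a
reference set of fully ranked expression profiles.

This follows the classic connectivity-map construction: a one-sided
Kolmogorov-Smirnov-style enrichment statistic per tag list, a raw instance
score that is zeroed when the up and down lists are enriched at the same
end of the ranking, batch-wide rescaling by the maximum absolute raw score,
per-(perturbagen, cell line) mean scores, and a permutation p-value
obtained by redrawing the signature's tags from the universe.

For a tag list of size t against a ranking of n tags, with V(1) <= ... <=
V(t) the sorted ranks of the tags::

    a = max_j ( j/t - V(j)/n )
    b = max_j ( V(j)/n - (j-1)/t )
    KS = a  if a > b  else  -b

so KS is positive when the tags crowd the top of the ranking (rank 1 =
most up-regulated) and negative when they crowd the bottom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RankedProfile",
    "TagSignature",
    "ConnectivityResult",
    "ks_enrichment",
    "instance_score",
    "scale_scores",
    "score_batch",
    "mean_scores_with_pvalues",
]


@dataclass(frozen=True)
class RankedProfile:
    """A reference expression instance: a total ranking of the tag universe
    produced by one perturbagen treatment in one cell line.

    ``order`` lists tags from rank 1 (most up-regulated) to rank n.
    """

    instance_id: str
    perturbagen: str
    cell_line: str
    order: tuple[str, ...]

    def __post_init__(self):
        order = tuple(self.order)
        if len(set(order)) != len(order) or not order:
            raise ValueError(
                "profile %r: ranking must be a nonempty permutation (no repeats)"
                % self.instance_id
            )
        object.__setattr__(self, "order", order)

    @property
    def n(self) -> int:
        return len(self.order)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.order)

    def rank_of(self, tag: str) -> int:
        """1-based rank of *tag*; raises KeyError naming an absent tag."""
        try:
            return self._rank_index()[tag]
        except KeyError:
            raise KeyError("tag %r absent from profile universe" % tag) from None

    def _rank_index(self) -> dict[str, int]:
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {t: r for r, t in enumerate(self.order, start=1)}
            object.__setattr__(self, "_idx", idx)
        return idx

    def reversed(self) -> "RankedProfile":
        """The same instance with the ranking turned upside down."""
        return RankedProfile(
            self.instance_id, self.perturbagen, self.cell_line, self.order[::-1]
        )


@dataclass(frozen=True)
class TagSignature:
    """Query signature: ordered up- and down-regulated tag lists.

    The two lists are disjoint; either may be empty but not both, so
    up-only (or down-only) queries are supported.
    """

    up: tuple[str, ...] = ()
    down: tuple[str, ...] = ()

    def __post_init__(self):
        up, down = tuple(self.up), tuple(self.down)
        if not up and not down:
            raise ValueError("signature needs at least one nonempty tag list")
        if len(set(up)) != len(up) or len(set(down)) != len(down):
            raise ValueError("repeated tag within a signature list")
        if set(up) & set(down):
            raise ValueError(
                "tags in both lists: %s" % sorted(set(up) & set(down))
            )
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)

    @property
    def tags(self) -> tuple[str, ...]:
        return self.up + self.down


@dataclass(frozen=True)
class ConnectivityResult:
    """Mean connectivity score and permutation p-value for one
    (perturbagen, cell line) combination."""

    perturbagen: str
    cell_line: str
    mean_score: float
    p_value: float
    n_instances: int

    def __post_init__(self):
        if not (-1.0 <= self.mean_score <= 1.0 + 1e-12):
            raise ValueError("mean score outside [-1, 1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p value outside (0, 1]")
        if self.n_instances < 1:
            raise ValueError("combination with no instances")


# ---------------------------------------------------------------------------
# KS enrichment
# ---------------------------------------------------------------------------

def ks_enrichment(tags: Sequence[str], profile: RankedProfile) -> float:
    """Signed KS enrichment of *tags* in the profile's ranking, in [-1, 1]."""
    t = len(tags)
    if t == 0:
        raise ValueError("empty tag list")
    n = profile.n
    ranks = sorted(profile.rank_of(tag) for tag in tags)
    v = np.asarray(ranks, dtype=float)
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


def _raw_from_sides(ks_up: float | None, ks_down: float | None) -> float:
    if ks_up is None:
        return -ks_down  # down-only query
    if ks_down is None:
        return ks_up  # up-only query
    same_sign = (ks_up > 0 and ks_down > 0) or (ks_up < 0 and ks_down < 0)
    return 0.0 if same_sign else ks_up - ks_down


def instance_score(sig: TagSignature, profile: RankedProfile) -> float:
    """Raw (unscaled) connectivity score of one instance.

    With both lists present the score is 0 when the up and down KS
    statistics share a sign (the signature is not coherently mimicked or
    reversed), otherwise ks_up - ks_down.  Batch rescaling into [-1, 1] is
    a separate step (`scale_scores` / `score_batch`) because the scale is
    defined over all instances queried together.
    """
    ks_up = ks_enrichment(sig.up, profile) if sig.up else None
    ks_down = ks_enrichment(sig.down, profile) if sig.down else None
    return _raw_from_sides(ks_up, ks_down)


def scale_scores(raw: Sequence[float]) -> np.ndarray:
    """Scale a batch of raw scores by the maximum absolute value.

    The scaled batch lies in [-1, 1] and its extreme instance attains
    magnitude 1.  A batch whose raw scores are all zero stays zero; an
    empty batch is an error.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise ValueError("empty batch: nothing to scale")
    m = np.max(np.abs(arr))
    return arr / m if m > 0 else arr.copy()


def score_batch(
    sig: TagSignature, profiles: Sequence[RankedProfile]
) -> np.ndarray:
    """Scaled instance scores for a batch of profiles, in profile order."""
    return scale_scores([instance_score(sig, p) for p in profiles])


# ---------------------------------------------------------------------------
# Vectorized engine for permutation testing
# ---------------------------------------------------------------------------

def _position_matrix(
    profiles: Sequence[RankedProfile],
) -> tuple[np.ndarray, dict[str, int]]:
    """(P, n) matrix of tag ranks per profile + tag->column index.

    All profiles must share one tag universe.
    """
    universe = sorted(profiles[0].universe)
    index = {t: i for i, t in enumerate(universe)}
    pos = np.empty((len(profiles), len(universe)), dtype=float)
    for i, prof in enumerate(profiles):
        if prof.universe != profiles[0].universe:
            raise ValueError(
                "profile %r has a different tag universe" % prof.instance_id
            )
        for r, tag in enumerate(prof.order, start=1):
            pos[i, index[tag]] = r
    return pos, index


def _ks_many(pos: np.ndarray, tag_idx: np.ndarray) -> np.ndarray:
    """KS statistic for many tag sets against many profiles.

    pos: (P, n) ranks; tag_idx: (m, t) column indices. Returns (m, P).
    """
    n = pos.shape[1]
    t = tag_idx.shape[1]
    v = np.sort(pos[:, tag_idx], axis=2)  # (P, m, t)
    j = np.arange(1, t + 1, dtype=float)
    a = (j / t - v / n).max(axis=2)  # (P, m)
    b = (v / n - (j - 1) / t).max(axis=2)
    return np.where(a > b, a, -b).T  # (m, P)


def _raw_many(
    pos: np.ndarray, up_idx: np.ndarray | None, down_idx: np.ndarray | None
) -> np.ndarray:
    """Raw scores (m, P) for m signatures given as index arrays."""
    if up_idx is None:
        return -_ks_many(pos, down_idx)
    if down_idx is None:
        return _ks_many(pos, up_idx)
    ku = _ks_many(pos, up_idx)
    kd = _ks_many(pos, down_idx)
    same = ((ku > 0) & (kd > 0)) | ((ku < 0) & (kd < 0))
    return np.where(same, 0.0, ku - kd)


def _scale_rows(raw: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(raw), axis=1, keepdims=True)
    m = np.where(m > 0, m, 1.0)
    return raw / m


def mean_scores_with_pvalues(
    sig: TagSignature,
    profiles: Sequence[RankedProfile],
    n_perm: int = 1000,
    seed: int = 0,
) -> list[ConnectivityResult]:
    """Per-(perturbagen, cell line) mean connectivity score with a
    permutation p-value.

    Scores are scaled batch-wide (over all given profiles) and averaged
    within each combination.  Each of the *n_perm* permutations redraws the
    signature's tags uniformly without replacement from the universe
    (preserving list sizes), rescores the whole batch under its own scale,
    and the p-value is the add-one estimate
    ``(1 + #{permuted |mean| >= observed |mean|}) / (1 + n_perm)``.
    Results are sorted by mean score descending.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty batch: no profiles")
    pos, index = _position_matrix(profiles)
    n = pos.shape[1]
    tu, td = len(sig.up), len(sig.down)
    for tag in sig.tags:
        if tag not in index:
            raise KeyError("tag %r absent from profile universe" % tag)

    def _idx(tags: tuple[str, ...]) -> np.ndarray | None:
        if not tags:
            return None
        return np.asarray([[index[t] for t in tags]], dtype=int)

    obs_raw = _raw_many(pos, _idx(sig.up), _idx(sig.down))  # (1, P)
    obs_scaled = _scale_rows(obs_raw)[0]  # (P,)

    # permuted signatures: each row a fresh draw of tu+td distinct columns
    rng = np.random.default_rng(seed)
    draw = np.argsort(rng.random((n_perm, n)), axis=1)[:, : tu + td]
    perm_up = draw[:, :tu] if tu else None
    perm_down = draw[:, tu:] if td else None
    perm_scaled = _scale_rows(_raw_many(pos, perm_up, perm_down))  # (n_perm, P)

    combos: dict[tuple[str, str], list[int]] = {}
    for i, prof in enumerate(profiles):
        combos.setdefault((prof.perturbagen, prof.cell_line), []).append(i)

    results = []
    for (pert, cell), idxs in combos.items():
        obs_mean = float(np.mean(obs_scaled[idxs]))
        perm_means = perm_scaled[:, idxs].mean(axis=1)
        exceed = int(np.sum(np.abs(perm_means) >= abs(obs_mean)))
        p = (1 + exceed) / (1 + n_perm)
        results.append(
            ConnectivityResult(
                perturbagen=pert,
                cell_line=cell,
                mean_score=obs_mean,
                p_value=p,
                n_instances=len(idxs),
            )
        )
    results.sort(key=lambda r: (-r.mean_score, r.perturbagen, r.cell_line))
    return results
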