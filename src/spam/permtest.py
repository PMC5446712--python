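"""Max/min-statistic permutation testing of two groups of vessel maps.

The test compares two groups of standardized maps pixel-wise while
controlling the family-wise error rate.  For every relabelling of the
subjects (exhaustive when feasible, otherwise a seeded Monte-Carlo sample
that always includes the original labelling) the mean difference map is
computed; each pixel is normalized by the standard deviation of its value
over all permutation difference maps; the per-permutation maximum (and,
for the negative direction, minimum) of the normalized — optionally
cluster-enhanced — map forms the null distribution.  The original map is
thresholded at empirical percentiles of those distributions, so a single
threshold controls the probability of any false-positive pixel.

Two exchangeability schemes are supported: unpaired (group labels of whole
subjects are permuted; C(n, k) assignments) and paired (each subject
contributes one image to each group and only within-subject swaps are
allowed; 2^(n/2) assignments).

The public surface follows the fitted-model convention: build a
:class:`PermutationTest` from the data, call :meth:`~PermutationTest.fit`,
and read estimates, thresholds and masks off the returned
:class:`PermutationResult`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .tfce import TFCEParams, tfce_enhance

__all__ = [
    "StudyDesign",
    "LabelAssignment",
    "NullDistributions",
    "PermutationResult",
    "PermutationTest",
    "unpaired_assignment_count",
    "total_assignments",
    "mean_difference",
    "enumerate_assignments",
    "null_distributions",
    "threshold",
    "run_test",
    "simulate_null_fwer",
]

DEFAULT_MAX_PERMUTATIONS = 5000
"""Cap on the number of assignments evaluated.

Exhaustive enumeration is used whenever the total count fits under the cap;
1000 permutations are generally sufficient for a stable approximate test."""


def _map_values(m) -> np.ndarray:
    values = getattr(m, "values", m)
    return np.asarray(values, dtype=float)


@dataclass(eq=False)
class StudyDesign:
    """Two groups of identically shaped maps, optionally paired.

    ``pair_index[i]`` gives the group-B index paired with group-A map ``i``
    (identity by default); it must be a bijection.
    """

    group_a: list
    group_b: list
    paired: bool = False
    pair_index: list[int] | None = None

    def __post_init__(self):
        self._a = np.stack([_map_values(m) for m in self.group_a])
        self._b = np.stack([_map_values(m) for m in self.group_b])
        if self._a.shape[1:] != self._b.shape[1:]:
            raise ValueError("all maps must share one shape")
        if len(self.group_a) == 0 or len(self.group_b) == 0:
            raise ValueError("both groups must be non-empty")
        if self.paired:
            if len(self.group_a) != len(self.group_b):
                raise ValueError("paired design requires equally sized groups")
            if self.pair_index is None:
                self.pair_index = list(range(len(self.group_a)))
            idx = np.asarray(self.pair_index, dtype=int)
            if sorted(idx.tolist()) != list(range(len(self.group_b))):
                raise ValueError("pair_index must be a bijection onto group B")

    @property
    def map_shape(self) -> tuple[int, ...]:
        return self._a.shape[1:]

    @property
    def n_a(self) -> int:
        return self._a.shape[0]

    @property
    def n_b(self) -> int:
        return self._b.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n_a

    def stacked(self) -> np.ndarray:
        """All maps, group A first, flattened to (n_subjects, n_pixels)."""
        n = self.n_a + self.n_b
        return np.concatenate([self._a, self._b]).reshape(n, -1)

    def paired_differences(self) -> np.ndarray:
        """Per-pair (A - B) maps flattened to (n_pairs, n_pixels)."""
        idx = np.asarray(self.pair_index, dtype=int)
        return (self._a - self._b[idx]).reshape(self.n_pairs, -1)


@dataclass(eq=False)
class LabelAssignment:
    """One permutation of the group labels.

    Unpaired: boolean mask over subjects (A-group first), True = assigned to
    group A; exactly ``n_a`` True entries.  Paired: sign vector over pairs,
    +1 = original orientation, -1 = swapped within the pair.
    """

    mask: np.ndarray
    paired: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask)


@dataclass(eq=False)
class NullDistributions:
    """Per-permutation maximum and minimum statistics."""

    max_values: np.ndarray
    min_values: np.ndarray
    n_permutations: int
    includes_original: bool = True

    def __post_init__(self):
        self.max_values = np.asarray(self.max_values, dtype=float)
        self.min_values = np.asarray(self.min_values, dtype=float)
        if len(self.max_values) != self.n_permutations or len(
            self.min_values
        ) != self.n_permutations:
            raise ValueError("distribution lengths must equal n_permutations")
        if np.any(self.max_values < self.min_values):
            raise ValueError("per-permutation max must be >= min")


def unpaired_assignment_count(n: int, k: int) -> int:
    """Number of distinct unpaired label assignments, C(n, k), exactly."""
    return math.comb(n, k)


def total_assignments(design: StudyDesign) -> int:
    """Total number of distinct label assignments for a design."""
    if design.paired:
        return 2 ** design.n_pairs
    return unpaired_assignment_count(design.n_a + design.n_b, design.n_a)


def mean_difference(group_a, group_b) -> np.ndarray:
    """mean(A) - mean(B), element-wise."""
    a = np.stack([_map_values(m) for m in group_a])
    b = np.stack([_map_values(m) for m in group_b])
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("all maps must share one shape")
    return a.mean(axis=0) - b.mean(axis=0)


def enumerate_assignments(
    design: StudyDesign,
    max_permutations: int = DEFAULT_MAX_PERMUTATIONS,
    seed: int = 0,
) -> list[LabelAssignment]:
    """Enumerate or sample label assignments; original labelling comes first.

    Exhaustive when the total count fits under ``max_permutations``.
    Otherwise a seeded Monte-Carlo sample is drawn: without replacement
    among distinct assignments when the total is at most 10x the cap, with
    replacement beyond that.  The original labelling is always included (and
    first), so observed statistics are ranked within their own null.
    """
    total = total_assignments(design)
    rng = np.random.default_rng(seed)
    if design.paired:
        p = design.n_pairs
        original = np.ones(p, dtype=int)
        if total <= max_permutations:
            # product() yields the all-ones (original) vector first
            signs = [
                np.asarray(s, dtype=int)
                for s in itertools.product((1, -1), repeat=p)
            ]
        elif total <= 10 * max_permutations:
            all_codes = rng.choice(total, size=max_permutations - 1, replace=False)
            signs = [original] + [
                1 - 2 * ((int(c) >> np.arange(p)) & 1) for c in all_codes
            ]
            signs = _dedup_against_first(signs)
        else:
            signs = [original] + [
                rng.choice((1, -1), size=p) for _ in range(max_permutations - 1)
            ]
        return [LabelAssignment(s, paired=True) for s in signs]

    n, k = design.n_a + design.n_b, design.n_a
    original = np.zeros(n, dtype=bool)
    original[:k] = True
    if total <= max_permutations:
        masks = []
        for combo in itertools.combinations(range(n), k):
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            masks.append(m)
        # combinations() yields (0..k-1) first, i.e. the original labelling
        return [LabelAssignment(m) for m in masks]
    if total <= 10 * max_permutations:
        combos = list(itertools.combinations(range(n), k))
        pick = rng.choice(len(combos), size=max_permutations - 1, replace=False)
        masks = [original]
        for c in pick:
            m = np.zeros(n, dtype=bool)
            m[list(combos[int(c)])] = True
            masks.append(m)
        masks = _dedup_against_first(masks)
        return [LabelAssignment(m) for m in masks]
    masks = [original]
    for _ in range(max_permutations - 1):
        m = np.zeros(n, dtype=bool)
        m[rng.choice(n, size=k, replace=False)] = True
        masks.append(m)
    return [LabelAssignment(m) for m in masks]


def _dedup_against_first(vectors: list[np.ndarray]) -> list[np.ndarray]:
    """Drop later duplicates of the force-included first (original) vector."""
    first = vectors[0]
    seen_first = False
    out = []
    for v in vectors:
        if np.array_equal(v, first):
            if seen_first:
                continue
            seen_first = True
        out.append(v)
    return out


def _assignment_weights(design: StudyDesign, assignments) -> np.ndarray:
    """Weight matrix turning stacked maps into per-assignment difference maps."""
    if design.paired:
        signs = np.stack([np.asarray(a.mask, dtype=float) for a in assignments])
        return signs / design.n_pairs
    n_a, n_b = design.n_a, design.n_b
    masks = np.stack([np.asarray(a.mask, dtype=bool) for a in assignments])
    return np.where(masks, 1.0 / n_a, -1.0 / n_b)


def _permutation_stack(
    design: StudyDesign,
    assignments,
    statistic_transform=None,
    include_original_in_sd: bool = True,
):
    """Difference maps, SD map, normalized (transformed) maps and extrema."""
    if len(assignments) < 2:
        raise ValueError("need at least two assignments")
    X = design.paired_differences() if design.paired else design.stacked()
    W = _assignment_weights(design, assignments)
    diffs = W @ X  # (n_assign, n_pixels)
    sd_rows = diffs if include_original_in_sd else diffs[1:]
    sd = sd_rows.std(axis=0, ddof=0)
    # pixels whose SD is zero (up to accumulation rounding) carry no evidence
    tiny = 1e4 * np.finfo(float).eps * max(float(np.abs(diffs).max()), 1e-300)
    sd = np.where(sd <= tiny, 0.0, sd)
    normalized = np.divide(
        diffs, sd[None, :], out=np.zeros_like(diffs), where=sd > 0
    )
    shape = design.map_shape
    if statistic_transform is not None:
        normalized = np.stack(
            [
                np.asarray(statistic_transform(row.reshape(shape)), dtype=float).ravel()
                for row in normalized
            ]
        )
    return {
        "diffs": diffs,
        "sd": sd.reshape(shape),
        "stats": normalized,
        "max": normalized.max(axis=1),
        "min": normalized.min(axis=1),
    }


def null_distributions(
    design: StudyDesign,
    assignments,
    statistic_transform=None,
    include_original_in_sd: bool = True,
) -> tuple[NullDistributions, np.ndarray]:
    """Max/min null distributions and the per-pixel SD map.

    The SD at each pixel is the population SD of its value over the mean
    difference maps of all assignments (original included by default); each
    difference map is divided by it before the optional transform.  Pixels
    with zero SD carry no evidence of a difference and are set to 0.
    """
    res = _permutation_stack(
        design, assignments, statistic_transform, include_original_in_sd
    )
    dists = NullDistributions(
        res["max"], res["min"], n_permutations=len(res["max"]), includes_original=True
    )
    return dists, res["sd"]


def threshold(dists: NullDistributions, alpha: float) -> tuple[float, float]:
    """Empirical percentile thresholds of the max and min distributions.

    ``t_upper`` is the ceil((1-alpha)*n)-th order statistic of the maxima
    (1-based, ascending), which guarantees family-wise error <= alpha under
    exhaustive enumeration; ``t_lower`` is the mirrored order statistic of
    the minima.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n = dists.n_permutations
    iu = int(math.ceil((1 - alpha) * n))
    iu = min(max(iu, 1), n)
    t_upper = float(np.sort(dists.max_values)[iu - 1])
    t_lower = float(np.sort(dists.min_values)[n - iu])
    return t_upper, t_lower


@dataclass(eq=False)
class PermutationResult:
    """Fitted permutation-test results.

    ``significance_mask`` is +1 where the (enhanced) normalized statistic of
    the original labelling exceeds ``t_upper``, -1 where it falls below
    ``t_lower``, 0 elsewhere.
    """

    mean_diff: np.ndarray
    sd_map: np.ndarray
    normalized_diff: np.ndarray
    enhanced_diff: np.ndarray | None
    t_upper: float
    t_lower: float
    significance_mask: np.ndarray
    alpha: float
    distributions: NullDistributions
    n_permutations: int
    seed: int
    paired: bool
    n_a: int
    n_b: int
    used_tfce: bool
    tfce_params: TFCEParams | None = None
    include_original_in_sd: bool = True

    @property
    def statistic_map(self) -> np.ndarray:
        """The map the thresholds were applied to."""
        return self.enhanced_diff if self.used_tfce else self.normalized_diff

    @property
    def n_significant(self) -> tuple[int, int]:
        return (
            int((self.significance_mask > 0).sum()),
            int((self.significance_mask < 0).sum()),
        )

    def summary(self) -> str:
        pos, neg = self.n_significant
        lines = [
            "Permutation test of two map groups",
            "=" * 44,
            f"{'design':<28}{'paired' if self.paired else 'unpaired'}",
            f"{'group sizes':<28}{self.n_a} vs {self.n_b}",
            f"{'map shape':<28}{self.mean_diff.shape}",
            f"{'permutations':<28}{self.n_permutations}"
            f" (original included)",
            f"{'alpha':<28}{self.alpha}",
            f"{'cluster enhancement':<28}{'TFCE' if self.used_tfce else 'none'}",
            f"{'seed':<28}{self.seed}",
            "-" * 44,
            f"{'max statistic (original)':<28}{self.statistic_map.max():.6g}",
            f"{'min statistic (original)':<28}{self.statistic_map.min():.6g}",
            f"{'upper threshold':<28}{self.t_upper:.6g}",
            f"{'lower threshold':<28}{self.t_lower:.6g}",
            f"{'pixels above threshold':<28}{pos}",
            f"{'pixels below threshold':<28}{neg}",
            "=" * 44,
        ]
        return "\n".join(lines)


class PermutationTest:
    """Max-statistic permutation test model for two groups of vessel maps.

    Parameters
    ----------
    group_a, group_b
        Lists of 2D arrays or :class:`~spam.unwarp.VesselMap` objects,
        identically shaped.
    paired
        Within-subject exchangeability: each subject contributed one map to
        each group and only within-pair swaps are permitted.
    pair_index
        Index of the group-B map paired with each group-A map.
    """

    def __init__(self, group_a, group_b, paired: bool = False, pair_index=None):
        self.design = StudyDesign(
            list(group_a), list(group_b), paired=paired, pair_index=pair_index
        )

    @classmethod
    def from_design(cls, design: StudyDesign) -> "PermutationTest":
        obj = cls.__new__(cls)
        obj.design = design
        return obj

    @classmethod
    def from_manifest(cls, manifest_path, paired: bool = False) -> "PermutationTest":
        """Build from a CSV manifest with columns map_path, group[, subject_id]."""
        from .io import read_manifest_design

        return cls.from_design(read_manifest_design(manifest_path, paired=paired))

    def fit(
        self,
        alpha: float = 0.05,
        max_permutations: int = DEFAULT_MAX_PERMUTATIONS,
        seed: int = 0,
        tfce: bool = False,
        tfce_params: TFCEParams | None = None,
        include_original_in_sd: bool = True,
    ) -> PermutationResult:
        """Run the full permutation pipeline and return the results object."""
        design = self.design
        assignments = enumerate_assignments(design, max_permutations, seed)
        params = tfce_params or TFCEParams()
        transform = (
            (lambda m: tfce_enhance(m, params).values) if tfce else None
        )
        res = _permutation_stack(
            design, assignments, transform, include_original_in_sd
        )
        shape = design.map_shape
        dists = NullDistributions(
            res["max"], res["min"], n_permutations=len(res["max"])
        )
        t_upper, t_lower = threshold(dists, alpha)
        stat0 = res["stats"][0].reshape(shape)
        mask = np.zeros(shape, dtype=int)
        mask[stat0 > t_upper] = 1
        mask[stat0 < t_lower] = -1
        norm0 = np.divide(
            res["diffs"][0].reshape(shape),
            res["sd"],
            out=np.zeros(shape),
            where=res["sd"] > 0,
        )
        return PermutationResult(
            mean_diff=res["diffs"][0].reshape(shape),
            sd_map=res["sd"],
            normalized_diff=norm0,
            enhanced_diff=stat0 if tfce else None,
            t_upper=t_upper,
            t_lower=t_lower,
            significance_mask=mask,
            alpha=alpha,
            distributions=dists,
            n_permutations=len(assignments),
            seed=seed,
            paired=design.paired,
            n_a=design.n_a,
            n_b=design.n_b,
            used_tfce=tfce,
            tfce_params=params if tfce else None,
            include_original_in_sd=include_original_in_sd,
        )


def run_test(
    design: StudyDesign,
    alpha: float = 0.05,
    max_permutations: int = DEFAULT_MAX_PERMUTATIONS,
    seed: int = 0,
    use_tfce: bool = False,
    tfce_params: TFCEParams | None = None,
    include_original_in_sd: bool = True,
) -> PermutationResult:
    """Functional wrapper around :class:`PermutationTest`."""
    return PermutationTest.from_design(design).fit(
        alpha=alpha,
        max_permutations=max_permutations,
        seed=seed,
        tfce=use_tfce,
        tfce_params=tfce_params,
        include_original_in_sd=include_original_in_sd,
    )


def simulate_null_fwer(
    n_repetitions: int = 500,
    n_per_group: int = 5,
    shape: tuple[int, int] = (40, 40),
    alpha: float = 0.05,
    max_permutations: int = 1000,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> float:
    """Empirical family-wise error rate under a pure-noise null.

    Each repetition draws both groups from the identical Gaussian noise
    model, runs the unpaired max-statistic test, and scores whether any
    pixel of the original labelling exceeds the upper threshold.  The
    returned fraction estimates the probability of any false-positive pixel
    and should match the nominal level ``alpha``.
    """
    from .synthetic import MapGroupSpec, make_map_groups

    seeds = np.random.SeedSequence(seed).generate_state(n_repetitions) % (2**31)
    hits = 0
    for r in range(n_repetitions):
        design = make_map_groups(
            MapGroupSpec(
                shape=shape,
                n_per_group=n_per_group,
                effect_size=0.0,
                noise_sd=noise_sd,
                seed=int(seeds[r]),
            )
        )
        result = run_test(
            design,
            alpha=alpha,
            max_permutations=max_permutations,
            seed=int(seeds[r]),
        )
        if bool((result.normalized_diff > result.t_upper).any()):
            hits += 1
    return hits / n_repetitions
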