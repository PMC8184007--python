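"""Image-based resampling null for filament-autophagosome colocalization.

Bootstrap-like null for a single fixed cell: keep the cell boundary and the
Bcl10 channel in place, rigidly rotate each segmented autophagosome by three
random axis angles, and re-place it uniformly inside the cell boundary,
rejecting positions that leave the boundary or overlap an already placed
autophagosome (overlap with Bcl10 is allowed - that is precisely what creates
null contacts).  Repeating the rearrangement builds the null distribution of
contact counts and contact locations against which the observed cell is
compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp, t as t_dist

from .contacts import (
    CellSummary,
    StructureMeasurements,
    find_contacts,
    locate_contact,
)

__all__ = [
    "NullEnsemble",
    "NullVerdict",
    "rotate_voxel_object",
    "rearrange_autophagosomes",
    "build_null",
    "compare_to_null",
]


@dataclass
class NullEnsemble:
    """Per-cell collection of resampling-trial statistics."""

    n_trials: int
    contact_counts: np.ndarray           # per trial
    end_distances: list[np.ndarray]      # per trial, filamentous contacts
    puncta_contact_counts: np.ndarray    # per trial
    n_failed: int = 0

    @property
    def mean(self) -> float:
        return float(self.contact_counts.mean())

    @property
    def ci95(self) -> tuple[float, float]:
        """t confidence interval of the mean contact count."""
        n = len(self.contact_counts)
        if n < 2:
            return self.mean, self.mean
        se = self.contact_counts.std(ddof=1) / np.sqrt(n)
        h = t_dist.ppf(0.975, n - 1) * se
        return self.mean - h, self.mean + h

    @property
    def trial_interval95(self) -> tuple[float, float]:
        """Interval covering the central 95% of null trial counts."""
        lo, hi = np.quantile(self.contact_counts, [0.025, 0.975])
        return float(lo), float(hi)

    @property
    def pooled_end_distances(self) -> np.ndarray:
        if not self.end_distances:
            return np.empty(0)
        return np.concatenate(self.end_distances)


@dataclass
class NullVerdict:
    """Observed cell vs. its rearrangement null."""

    observed_contacts: int
    null_mean: float
    null_ci95: tuple[float, float]
    null_trial_interval95: tuple[float, float]
    excess: float                        # observed - null mean
    exceeds_ci: bool                     # observed above the mean's 95% CI
    outside_trial_interval: bool         # observed outside the trial interval
    ks_statistic: float = np.nan         # end-distance distributions
    ks_pvalue: float = np.nan
    observed_puncta_contacts: int = 0
    null_puncta_contact_mean: float = np.nan


def rotate_voxel_object(
    coords: np.ndarray, angles: np.ndarray,
) -> np.ndarray:
    """Rigidly rotate a voxel set about its centroid.

    The rotation (axis angles x, y, z in radians, applied about the object
    centroid) is realized by nearest-neighbor pull-back resampling: an output
    voxel is occupied iff its center, rotated back, lands in the source voxel
    set.  This preserves shape and voxel count to within a few percent for
    solid objects.  Returns offsets relative to the rotated object's centroid
    voxel.
    """
    pts = coords.astype(float)
    centroid = pts.mean(axis=0)
    ax, ay, az = angles
    rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0],
                   [0, 0, 1]])
    rot = rz @ ry @ rx
    src = pts - centroid
    # nearest-neighbor pull-back: an output voxel is occupied iff its center,
    # rotated back, lands inside the source voxel set (volume-preserving, no
    # rounding holes to close)
    lo = np.floor(src.min(axis=0)).astype(np.int64) - 1
    hi = np.ceil(src.max(axis=0)).astype(np.int64) + 2
    grid = np.zeros(hi - lo, dtype=bool)
    grid[tuple((np.round(src).astype(np.int64) - lo).T)] = True
    cand = np.argwhere(np.ones(hi - lo, dtype=bool)) + lo
    back = cand @ rot  # == rot.T applied to each candidate (inverse rotation)
    bij = np.round(back).astype(np.int64) - lo
    ok = np.all((bij >= 0) & (bij < grid.shape), axis=1)
    hit = np.zeros(len(cand), dtype=bool)
    hit[ok] = grid[tuple(bij[ok].T)]
    out = cand[hit]
    if len(out) == 0:
        out = np.zeros((1, 3), dtype=np.int64)
    return out - np.round(out.mean(axis=0)).astype(np.int64)


def rearrange_autophagosomes(
    cell_mask: np.ndarray,
    lc3_labels: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 10_000,
    redraw_rotation: bool = False,
    _vesicles: list[tuple[int, np.ndarray]] | None = None,
    _inside: np.ndarray | None = None,
) -> np.ndarray:
    """One random rearrangement of the segmented autophagosomes.

    Each labeled object is rotated by three uniform angles in [0, 2pi) and
    placed with its centroid at a uniformly drawn voxel inside the cell mask;
    a placement is rejected (and the location redrawn; the rotation too when
    ``redraw_rotation``) if any voxel falls outside the mask or overlaps an
    already placed object.  The Bcl10 channel plays no role in rejection.
    Returns the rearranged label volume; raises naming the vesicle if a
    placement cannot be found within ``max_tries``.
    """
    shape = cell_mask.shape
    inside = _inside if _inside is not None else np.argwhere(cell_mask)
    if inside.size == 0:
        raise ValueError("cell mask is empty")
    out = np.zeros_like(lc3_labels)
    occupied = np.zeros(shape, dtype=bool)
    if _vesicles is None:
        ids = np.unique(lc3_labels)
        _vesicles = [(int(v), np.argwhere(lc3_labels == v)) for v in ids[ids > 0]]
    for vid, coords in _vesicles:
        offsets = rotate_voxel_object(coords, rng.uniform(0, 2 * np.pi, 3))
        placed = False
        for attempt in range(max_tries):
            if redraw_rotation and attempt > 0:
                offsets = rotate_voxel_object(coords, rng.uniform(0, 2 * np.pi, 3))
            anchor = inside[rng.integers(len(inside))]
            pos = offsets + anchor
            if np.any(pos < 0) or np.any(pos >= shape):
                continue
            ix = tuple(pos.T)
            if not cell_mask[ix].all():
                continue
            if occupied[ix].any():
                continue
            out[ix] = vid
            occupied[ix] = True
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place autophagosome {vid} within {max_tries} tries"
            )
    return out


def build_null(
    cell_mask: np.ndarray,
    bcl10_labels: np.ndarray,
    lc3_labels: np.ndarray,
    measurements: dict[int, StructureMeasurements],
    n_trials: int = 100,
    seed: int = 0,
    max_tries: int = 10_000,
    min_success: float = 0.9,
    with_distances: bool = True,
) -> NullEnsemble:
    """Run ``n_trials`` rearrangements and collect null contact statistics.

    Failed placements abort their trial; the ensemble requires at least
    ``min_success`` of trials to succeed.  Deterministic in ``seed``.
    ``with_distances=False`` skips contact localization when only counts are
    needed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    counts, puncta_counts, dists = [], [], []
    n_failed = 0
    ids = np.unique(lc3_labels)
    vesicles = [(int(v), np.argwhere(lc3_labels == v)) for v in ids[ids > 0]]
    inside = np.argwhere(cell_mask)
    for trial in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([seed, trial]))
        try:
            rearranged = rearrange_autophagosomes(
                cell_mask, lc3_labels, rng, max_tries,
                _vesicles=vesicles, _inside=inside)
        except RuntimeError:
            n_failed += 1
            continue
        contacts = find_contacts(bcl10_labels, rearranged)
        ed = []
        n_punc = 0
        if with_distances:
            for c in contacts:
                locate_contact(c, measurements[c.bcl10_structure_id])
                if c.contact_class == "P":
                    n_punc += 1
                elif np.isfinite(c.end_distance):
                    ed.append(c.end_distance)
        counts.append(len(contacts))
        puncta_counts.append(n_punc)
        dists.append(np.array(ed))
    if len(counts) < min_success * n_trials:
        raise RuntimeError(
            f"only {len(counts)}/{n_trials} rearrangement trials succeeded"
        )
    return NullEnsemble(
        n_trials=len(counts),
        contact_counts=np.array(counts),
        end_distances=dists,
        puncta_contact_counts=np.array(puncta_counts),
        n_failed=n_failed,
    )


def compare_to_null(observed: CellSummary, null: NullEnsemble) -> NullVerdict:
    """Compare the observed cell against its rearrangement null.

    Reports the contact-count excess over the null mean, whether the observed
    count exceeds the 95% CI of the null mean and whether it falls outside
    the central 95% of null trials, and a two-sample KS comparison of the
    end-distance distributions.
    """
    lo, hi = null.ci95
    tlo, thi = null.trial_interval95
    obs = observed.n_contacts
    pooled = null.pooled_end_distances
    ks_stat, ks_p = np.nan, np.nan
    if len(observed.contact_end_distances) >= 2 and len(pooled) >= 2:
        ks_stat, ks_p = ks_2samp(observed.contact_end_distances, pooled)
    return NullVerdict(
        observed_contacts=obs,
        null_mean=null.mean,
        null_ci95=(lo, hi),
        null_trial_interval95=(tlo, thi),
        excess=obs - null.mean,
        exceeds_ci=obs > hi,
        outside_trial_interval=not (tlo <= obs <= thi),
        ks_statistic=float(ks_stat),
        ks_pvalue=float(ks_p),
        observed_puncta_contacts=observed.n_puncta_contacts,
        null_puncta_contact_mean=float(null.puncta_contact_counts.mean())
        if len(null.puncta_contact_counts) else np.nan,
    )
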