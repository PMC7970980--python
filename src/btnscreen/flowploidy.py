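"""DNA-content flow cytometry: ploidy peak detection and DN classification.

A specimen's hemolymph yields a 1-D list of per-event DNA-fluorescence
intensities (pre-gated upstream on the instrument: scatter gating and
doublet removal are not modeled here).  Healthy mussel hemocytes produce a
single diploid peak, optionally with a small (< 5 %) tetraploid shoulder of
normally proliferating cells.  Disseminated neoplasia adds a population of
aneuploid cells whose DNA content, expressed relative to the specimen's own
diploid peak, typically falls between 3.7 n and 5.2 n and whose share of
events can approach 100 % in heavy disease.

The analysis is deliberately simple and fully testable: histogram ->
smoothed local-maxima peak detection -> per-bin gate assignment (nearest
peak within 3 sigma) -> ploidy labelling relative to the diploid anchor ->
healthy / DN-suggested classification.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DiagnosisError, InputError

HEALTHY = "healthy"
DN_SUGGESTED = "dn_suggested"
AMBIGUOUS_PROLIFERATIVE = "ambiguous-proliferative"

DIPLOID = "diploid"
TETRAPLOID = "tetraploid"
ANEUPLOID = "aneuploid"

#: fewer events than this triggers a warning (screening convention)
MIN_RECOMMENDED_EVENTS = 10_000

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class FlowEventSet:
    """1-D fluorescence event list for one specimen."""

    specimen_id: str
    intensities: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise InputError("intensities must be one-dimensional")
        if np.any(self.intensities < 0):
            raise InputError("negative fluorescence intensities")
        if self.n_events < MIN_RECOMMENDED_EVENTS:
            warnings.warn(
                f"{self.specimen_id}: only {self.n_events} events "
                f"(< {MIN_RECOMMENDED_EVENTS} recommended)",
                stacklevel=2,
            )

    @property
    def n_events(self) -> int:
        return int(self.intensities.size)


@dataclass
class Histogram:
    counts: np.ndarray
    edges: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())


@dataclass
class PloidyPeak:
    """One detected fluorescence peak."""

    mean_intensity: float
    fraction: float
    relative_ploidy: float | None = None
    label: str | None = None


@dataclass
class DNDiagnosis:
    specimen_id: str
    status: str
    aneuploid_fraction: float
    peaks: list[PloidyPeak] = field(default_factory=list)


def build_histogram(events: FlowEventSet, n_bins: int = 256) -> Histogram:
    """Bin event intensities over [0, max]."""
    if n_bins < 16:
        raise InputError("n_bins must be >= 16")
    if events.n_events == 0:
        raise InputError("empty event list")
    top = float(events.intensities.max())
    if top <= 0:
        top = 1.0
    counts, edges = np.histogram(events.intensities, bins=n_bins, range=(0.0, top))
    return Histogram(counts=counts, edges=edges)


def detect_peaks(
    histogram: Histogram,
    min_fraction: float = 0.01,
    min_separation: float = 1.05,
    smooth_sigma: float = 1.5,
    max_peaks: int = 8,
) -> list[PloidyPeak]:
    """Locate fluorescence peaks in a binned histogram.

    Seeding walks the Gaussian-smoothed counts, repeatedly taking the
    highest unmasked bin as a candidate peak, estimating its sigma from the
    half-height width, and masking its +/- 3 sigma neighbourhood; this finds
    minority peaks (a few percent of events) sitting next to a dominant one,
    which a single prominence threshold misses.  Every bin is then assigned
    to the nearest seed within 3 sigma, per-seed means and fractions are
    recomputed from the raw counts, seeds closer than ``min_separation``
    (ratio of means) are merged, and seeds holding less than ``min_fraction``
    of events are dropped with their bins returned to the survivors.
    Returned peaks are ordered by mean intensity; fractions sum to <= 1
    (events outside every gate stay unassigned).
    """
    counts = np.asarray(histogram.counts, dtype=float)
    if counts.size == 0 or counts.sum() == 0:
        raise InputError("empty histogram")
    total = counts.sum()
    centers = histogram.centers
    binwidth = float(histogram.edges[1] - histogram.edges[0])
    n = counts.size

    smoothed = gaussian_filter1d(counts, sigma=smooth_sigma, mode="nearest")
    floor = max(3.0, 1e-4 * total)

    masked = np.zeros(n, dtype=bool)
    seed_idx: list[int] = []
    seed_sigma: list[float] = []
    while len(seed_idx) < max_peaks:
        avail = np.flatnonzero(~masked)
        if avail.size == 0:
            break
        i = int(avail[np.argmax(smoothed[avail])])
        if smoothed[i] < floor:
            break
        at_mask_edge = (i > 0 and masked[i - 1]) or (i < n - 1 and masked[i + 1])
        if at_mask_edge and seed_idx:
            masked[i] = True  # shoulder of an already-masked peak
            continue
        sig_b = _half_width_sigma(smoothed, i)
        seed_idx.append(i)
        seed_sigma.append(sig_b)
        lo = max(0, i - int(np.ceil(3 * sig_b)))
        hi = min(n, i + int(np.ceil(3 * sig_b)) + 1)
        masked[lo:hi] = True

    if not seed_idx:
        seed_idx = [int(np.argmax(smoothed))]
        seed_sigma = [_half_width_sigma(smoothed, seed_idx[0])]

    means = [float(centers[i]) for i in seed_idx]
    sigmas = [s * binwidth for s in seed_sigma]

    while True:
        means, sigmas = _merge_seeds(means, sigmas, min_separation)
        stats = _assign_bins(counts, centers, means, sigmas, total, binwidth)
        live = [k for k, st in enumerate(stats) if st is not None]
        if not live:
            raise DiagnosisError("no events fall within any peak gate")
        means = [stats[k][0] for k in live]
        sigmas = [stats[k][2] for k in live]
        fracs = [stats[k][1] for k in live]
        if len(means) == 1 or min(fracs) >= min_fraction:
            break
        drop = int(np.argmin(fracs))
        del means[drop], sigmas[drop]

    order = np.argsort(means)
    return [
        PloidyPeak(mean_intensity=means[k], fraction=fracs[k]) for k in order
    ]


def _half_width_sigma(smoothed: np.ndarray, i: int) -> float:
    """Sigma estimate (in bins) from the half-height width around bin i."""
    half = smoothed[i] / 2.0
    left = i
    while left > 0 and smoothed[left] > half:
        left -= 1
    right = i
    n = smoothed.size
    while right < n - 1 and smoothed[right] > half:
        right += 1
    hwhm = max(0.5 * ((i - left) + (right - i)), 1.0)
    return max(2.0 * hwhm / _FWHM_TO_SIGMA, 0.8)


def _assign_bins(counts, centers, means, sigmas, total, binwidth):
    """Nearest-seed (z-score) bin assignment within 3 sigma.

    Returns per-seed (refined_mean, fraction, refined_sigma) or None for
    seeds that captured no events.
    """
    means = np.asarray(means, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    z = np.abs(centers[None, :] - means[:, None]) / sigmas[:, None]
    z[z > 3.0] = np.inf
    owner = np.argmin(z, axis=0)
    owner[np.all(np.isinf(z), axis=0)] = -1
    out = []
    for k in range(means.size):
        mask = owner == k
        mass = counts[mask].sum()
        if mass <= 0:
            out.append(None)
            continue
        mean = float(np.average(centers[mask], weights=counts[mask]))
        var = float(np.average((centers[mask] - mean) ** 2, weights=counts[mask]))
        sigma = max(np.sqrt(var), binwidth)
        out.append((mean, float(mass / total), sigma))
    return out


def _merge_seeds(means, sigmas, min_separation):
    """Merge seeds whose mean ratio falls below min_separation."""
    order = np.argsort(means)
    means = [means[k] for k in order]
    sigmas = [sigmas[k] for k in order]
    out_m: list[float] = []
    out_s: list[float] = []
    for m, s in zip(means, sigmas):
        if out_m and m < out_m[-1] * min_separation:
            out_m[-1] = 0.5 * (out_m[-1] + m)
            out_s[-1] = max(out_s[-1], s)
        else:
            out_m.append(m)
            out_s.append(s)
    return out_m, out_s


def assign_ploidy(
    peaks: list[PloidyPeak],
    diploid_anchor_fraction: float = 0.01,
    tetraploid_tolerance: float = 0.3,
    tetraploid_max_fraction: float = 0.05,
) -> list[PloidyPeak]:
    """Label peaks with ploidy relative to the diploid anchor.

    The anchor is the lowest-mean peak holding at least
    ``diploid_anchor_fraction`` of events — not the largest peak, because in
    heavy disease the diploid population can be a small minority.  Every
    other peak gets ``relative_ploidy = 2 * mean / anchor_mean``.

    The tetraploid label exists to excuse the small admixture of normally
    proliferating (G2/M) cells seen in healthy animals, so it applies only
    to peaks that are both near 4.0 n (within ``tetraploid_tolerance``) and
    small (fraction below ``tetraploid_max_fraction``).  A *large*
    near-tetraploid population is not normal proliferation and is labelled
    aneuploid — observed disease ploidies straddle 4 n, and excusing them by
    proximity to 4.0 alone would wave heavy disease through as healthy.
    """
    if not peaks:
        raise DiagnosisError("no peaks to label")
    anchors = [p for p in peaks if p.fraction >= diploid_anchor_fraction]
    if not anchors:
        raise DiagnosisError("no peak qualifies as the diploid anchor")
    anchor = min(anchors, key=lambda p: p.mean_intensity)
    labeled = []
    for p in peaks:
        rp = 2.0 * p.mean_intensity / anchor.mean_intensity
        if p is anchor:
            label, rp = DIPLOID, 2.0
        elif (
            abs(rp - 4.0) <= tetraploid_tolerance
            and p.fraction < tetraploid_max_fraction
        ):
            label = TETRAPLOID
        else:
            label = ANEUPLOID
        labeled.append(
            PloidyPeak(
                mean_intensity=p.mean_intensity,
                fraction=p.fraction,
                relative_ploidy=rp,
                label=label,
            )
        )
    return labeled


def classify_dn(
    peaks: list[PloidyPeak],
    min_aneuploid_fraction: float = 0.05,
    max_tetraploid_fraction: float = 0.05,
    specimen_id: str = "",
) -> DNDiagnosis:
    """Healthy vs DN-suggested from labelled peaks.

    Healthy: a lone diploid peak, or diploid plus a tetraploid peak holding
    fewer than 5 % of events (normal proliferation).  DN-suggested: any
    aneuploid peak at or above ``min_aneuploid_fraction``.  A tetraploid
    fraction >= 5 % with no aneuploid peak is flagged ambiguous-proliferative
    rather than forced into either class.
    """
    if any(p.label is None for p in peaks):
        raise DiagnosisError("peaks must be labelled by assign_ploidy first")
    aneuploid = [p for p in peaks if p.label == ANEUPLOID]
    aneuploid_fraction = float(sum(p.fraction for p in aneuploid))
    tetraploid_fraction = float(
        sum(p.fraction for p in peaks if p.label == TETRAPLOID)
    )
    if any(p.fraction >= min_aneuploid_fraction for p in aneuploid):
        status = DN_SUGGESTED
    elif tetraploid_fraction >= max_tetraploid_fraction:
        status = AMBIGUOUS_PROLIFERATIVE
    else:
        status = HEALTHY
    return DNDiagnosis(
        specimen_id=specimen_id,
        status=status,
        aneuploid_fraction=aneuploid_fraction,
        peaks=peaks,
    )


def analyze_events(
    events: FlowEventSet,
    n_bins: int = 128,
    min_fraction: float = 0.01,
    min_separation: float = 1.05,
    diploid_anchor_fraction: float = 0.01,
    tetraploid_tolerance: float = 0.3,
    min_aneuploid_fraction: float = 0.05,
) -> DNDiagnosis:
    """Full per-specimen chain: histogram -> peaks -> ploidy -> diagnosis."""
    hist = build_histogram(events, n_bins=n_bins)
    peaks = detect_peaks(hist, min_fraction=min_fraction, min_separation=min_separation)
    labeled = assign_ploidy(
        peaks,
        diploid_anchor_fraction=diploid_anchor_fraction,
        tetraploid_tolerance=tetraploid_tolerance,
    )
    return classify_dn(
        labeled,
        min_aneuploid_fraction=min_aneuploid_fraction,
        specimen_id=events.specimen_id,
    )


def prevalence_percent(n_positive: int, n_screened: int) -> int:
    """Screening prevalence as a whole percent (integer rounding)."""
    if n_screened <= 0:
        raise InputError("n_screened must be positive")
    return int(round(100.0 * n_positive / n_screened))
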