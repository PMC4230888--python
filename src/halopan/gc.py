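"""Contig-aware sliding-window %G+C landscapes.

%G+C is computed in fixed windows (default 100 bp, 20 bp step) along
each contig; the terminal sub-window residue of each contig is skipped
and windows with more than 10% ambiguous nucleotides are imputed to the
contig mean. The window series is then segmented by penalized
change-in-mean detection (binary segmentation with a BIC-style penalty,
or an exact dynamic program for short series); segments whose mean
diverges from the contig mean by at least a threshold become divergent
regions. Annotated features inside those regions are extracted and
protein families tested for fold-enrichment among them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import FamilySet
from .io import AMBIGUOUS_NUCLEOTIDES, ContigSet, Feature, FeatureTable


@dataclass
class GcScanConfig:
    window_bp: int = 100
    step_bp: int = 20
    ambiguity_fraction_max: float = 0.10

    def __post_init__(self) -> None:
        if not (self.window_bp >= self.step_bp >= 1):
            raise ValueError("need window_bp >= step_bp >= 1")


@dataclass
class GcProfile:
    """Windowed %G+C series for one genome.

    ``windows`` columns: contig_id, start (bp, 0-based), gc (percent),
    imputed (ambiguity flag). Means are computed over non-imputed
    windows only.
    """

    species_id: str
    windows: pd.DataFrame
    contig_means: dict[str, float]
    genome_mean: float
    config: GcScanConfig

    def contig_series(self, contig_id: str) -> pd.DataFrame:
        return self.windows[self.windows.contig_id == contig_id].reset_index(drop=True)


@dataclass
class Segment:
    start_window: int  # index into the contig's window series
    end_window: int    # exclusive
    mean: float


@dataclass
class Segmentation:
    """Per-contig changepoints, segment means and divergent regions."""

    species_id: str
    changepoints: dict[str, list[int]]          # per-contig window indices
    segments: dict[str, list[Segment]]
    divergent_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    # (contig_id, start_bp, end_bp, segment mean %G+C)


def gc_windows(contigs: ContigSet, config: GcScanConfig | None = None) -> GcProfile:
    """Sliding-window %G+C for every contig of a genome.

    %G+C = 100*(G+C)/(window length - ambiguous bases). Windows whose
    ambiguous fraction exceeds ``ambiguity_fraction_max`` are assigned
    the contig mean and flagged as imputed. Contigs shorter than one
    window contribute no windows.
    """
    config = config or GcScanConfig()
    w, step = config.window_bp, config.step_bp
    rows = []
    for cid, seq in contigs.contigs:
        L = len(seq)
        if L < w:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_amb = np.isin(arr, [ord(c) for c in AMBIGUOUS_NUCLEOTIDES])
        gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
        amb_cum = np.concatenate([[0], np.cumsum(is_amb)])
        starts = np.arange(0, L - w + 1, step)
        gc_counts = gc_cum[starts + w] - gc_cum[starts]
        amb_counts = amb_cum[starts + w] - amb_cum[starts]
        imputed = amb_counts > config.ambiguity_fraction_max * w
        denom = np.maximum(w - amb_counts, 1)
        gc_pct = 100.0 * gc_counts / denom
        for s, g, imp in zip(starts, gc_pct, imputed):
            rows.append((cid, int(s), float(g), bool(imp)))
    windows = pd.DataFrame(rows, columns=["contig_id", "start", "gc", "imputed"])
    contig_means: dict[str, float] = {}
    for cid in windows.contig_id.unique():
        sub = windows[(windows.contig_id == cid) & (~windows.imputed)]
        contig_means[cid] = float(sub.gc.mean()) if len(sub) else float("nan")
    # imputed windows take the contig mean
    for cid, mean in contig_means.items():
        mask = (windows.contig_id == cid) & windows.imputed
        windows.loc[mask, "gc"] = mean
    clean = windows[~windows.imputed]
    genome_mean = float(clean.gc.mean()) if len(clean) else float("nan")
    return GcProfile(
        species_id=contigs.species_id,
        windows=windows,
        contig_means=contig_means,
        genome_mean=genome_mean,
        config=config,
    )


# ---------------------------------------------------------------------------
# Change-in-mean segmentation
# ---------------------------------------------------------------------------

def _sse(cum: np.ndarray, cum2: np.ndarray, i: int, j: int) -> float:
    """Within-segment sum of squared deviations for x[i:j]."""
    n = j - i
    s = cum[j] - cum[i]
    s2 = cum2[j] - cum2[i]
    return s2 - s * s / n


def _binary_segmentation(x: np.ndarray, penalty: float, min_len: int) -> list[int]:
    cum = np.concatenate([[0.0], np.cumsum(x)])
    cum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cps: list[int] = []

    def recurse(i: int, j: int) -> None:
        if j - i < 2 * min_len:
            return
        base = _sse(cum, cum2, i, j)
        ks = np.arange(i + min_len, j - min_len + 1)
        gains = np.array([base - _sse(cum, cum2, i, k) - _sse(cum, cum2, k, j) for k in ks])
        best = int(np.argmax(gains))
        if gains[best] > penalty:
            k = int(ks[best])
            cps.append(k)
            recurse(i, k)
            recurse(k, j)

    recurse(0, len(x))
    return _refine(x, sorted(cps), cum, cum2, min_len)


def _refine(x, cps, cum, cum2, min_len, passes: int = 2) -> list[int]:
    """Re-locate each changepoint between its neighbors.

    Splits found while an interval still contained several true
    changepoints are biased; re-estimating each one as the single best
    split between its neighboring changepoints removes that bias.
    """
    n = len(x)
    for _ in range(passes):
        moved = False
        for idx, cp in enumerate(cps):
            lo = cps[idx - 1] if idx > 0 else 0
            hi = cps[idx + 1] if idx + 1 < len(cps) else n
            ks = np.arange(lo + min_len, hi - min_len + 1)
            if len(ks) == 0:
                continue
            base = _sse(cum, cum2, lo, hi)
            gains = base - np.array(
                [_sse(cum, cum2, lo, k) + _sse(cum, cum2, k, hi) for k in ks]
            )
            best = int(ks[int(np.argmax(gains))])
            if best != cp:
                cps[idx] = best
                moved = True
        cps = sorted(cps)
        if not moved:
            break
    return cps


def _exact_segmentation(x: np.ndarray, penalty: float, min_len: int) -> list[int]:
    """Optimal partitioning (O(n^2) dynamic program) minimizing
    sum of segment SSEs + penalty per changepoint."""
    n = len(x)
    cum = np.concatenate([[0.0], np.cumsum(x)])
    cum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    back = np.zeros(n + 1, dtype=int)
    for j in range(min_len, n + 1):
        i = np.arange(0, j - min_len + 1)
        seg_n = j - i
        s = cum[j] - cum[i]
        s2 = cum2[j] - cum2[i]
        costs = F[i] + (s2 - s * s / seg_n) + penalty
        best = int(np.argmin(costs))
        F[j] = costs[best]
        back[j] = i[best]
    cps = []
    j = n
    while j > 0:
        i = back[j]
        if i > 0:
            cps.append(i)
        j = i
    return sorted(cps)


def default_penalty(x: np.ndarray, correlation_lag: int = 1) -> float:
    """BIC-style penalty ``2 * sigma^2 * log(n) * correlation_lag``.

    sigma is estimated robustly (scaled median absolute deviation) from
    differences at *correlation_lag*, the smallest lag at which windows
    no longer overlap — overlapping windows share most of their bases,
    so first differences badly underestimate the marginal noise and the
    series behaves like a moving average with roughly ``n / lag``
    effective observations; the lag factor compensates.
    """
    lag = max(1, correlation_lag)
    diffs = x[lag:] - x[:-lag]
    sigma = np.median(np.abs(diffs - np.median(diffs))) / 0.6745 / np.sqrt(2)
    sigma = max(sigma, 1e-9)
    return 2.0 * sigma * sigma * np.log(len(x)) * lag


def segment_series(
    x: np.ndarray,
    penalty: float | None = None,
    min_segment_windows: int = 10,
    method: str = "binseg",
    correlation_lag: int = 1,
) -> list[int]:
    """Changepoints of a single window-mean series (indices into *x*)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * min_segment_windows:
        return []
    pen = default_penalty(x, correlation_lag) if penalty is None else penalty
    if method == "exact":
        return _exact_segmentation(x, pen, min_segment_windows)
    if method == "binseg":
        return _binary_segmentation(x, pen, min_segment_windows)
    raise ValueError(f"unknown method {method!r}")


def segment(
    profile: GcProfile,
    penalty: float | None = None,
    min_segment_windows: int = 10,
    divergence_min: float = 5.0,
    method: str = "binseg",
) -> Segmentation:
    """Segment each contig's window series at mean shifts.

    *penalty* is the cost of adding a changepoint; ``None`` selects the
    BIC-style default of :func:`default_penalty` per contig, with the
    correlation lag taken from the window/step overlap. Segments whose
    mean differs from the contig mean by at least *divergence_min*
    percentage points become divergent regions (genomic bp intervals).
    ``method`` is ``"binseg"`` (binary segmentation) or ``"exact"``
    (optimal partitioning; quadratic, for short series).
    """
    cfg = profile.config
    lag = max(1, cfg.window_bp // cfg.step_bp)
    changepoints: dict[str, list[int]] = {}
    segments: dict[str, list[Segment]] = {}
    regions: list[tuple[str, int, int, float]] = []
    for cid in profile.windows.contig_id.unique():
        series = profile.contig_series(cid)
        x = series.gc.to_numpy(float)
        if len(x) < 2 * min_segment_windows:
            changepoints[cid] = []
            segments[cid] = [Segment(0, len(x), float(x.mean()))] if len(x) else []
            continue
        cps = segment_series(
            x, penalty=penalty, min_segment_windows=min_segment_windows,
            method=method, correlation_lag=lag,
        )
        changepoints[cid] = cps
        bounds = [0] + cps + [len(x)]
        segs = [
            Segment(a, b, float(x[a:b].mean())) for a, b in zip(bounds[:-1], bounds[1:])
        ]
        segments[cid] = segs
        cmean = profile.contig_means[cid]
        starts = series.start.to_numpy()
        for s in segs:
            if abs(s.mean - cmean) >= divergence_min:
                start_bp = int(starts[s.start_window])
                end_bp = int(starts[s.end_window - 1]) + cfg.window_bp
                regions.append((cid, start_bp, end_bp, s.mean))
    return Segmentation(
        species_id=profile.species_id,
        changepoints=changepoints,
        segments=segments,
        divergent_regions=regions,
    )


def extract_region_features(
    segmentation: Segmentation, features: FeatureTable, mode: str = "midpoint"
) -> list[Feature]:
    """Features lying inside divergent regions.

    ``midpoint`` (default): the feature midpoint falls inside a region;
    ``overlap``: any overlap counts.
    """
    region_contigs = {r[0] for r in segmentation.divergent_regions}
    known = {f.contig_id for f in features.features}
    missing = region_contigs - known
    if missing:
        raise ValueError(f"contig IDs not in the feature table: {sorted(missing)}")
    out: list[Feature] = []
    for f in features.features:
        for cid, start, end, _mean in segmentation.divergent_regions:
            if f.contig_id != cid:
                continue
            if mode == "midpoint":
                hit = start <= f.midpoint < end
            elif mode == "overlap":
                hit = f.start < end and start < f.end
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if hit:
                out.append(f)
                break
    return out


@dataclass
class EnrichmentRow:
    family_id: str
    count_in_regions: int
    count_total: int
    region_feature_total: int
    genome_feature_total: int
    annotated: bool = True

    @property
    def fold(self) -> float:
        region_freq = self.count_in_regions / self.region_feature_total
        genome_freq = self.count_total / self.genome_feature_total
        return region_freq / genome_freq if genome_freq > 0 else float("inf")


def enrich(
    region_features: list[Feature],
    all_features: list[Feature],
    feature_family: dict[str, str],
    families: FamilySet | None = None,
    min_members: int = 5,
    min_fold: float = 8.0,
) -> list[EnrichmentRow]:
    """Fold-enrichment of protein families among divergent-region features.

    fold = (family's share of region features) / (family's share of all
    features). Reported rows need ``count_total >= min_members`` and
    ``fold >= min_fold``. Families whose members carry no annotation
    are flagged (``annotated=False``) when *families* provides the
    annotation census via ``species_of``-keyed records — here simply
    any feature with non-empty annotation text marks the family as
    annotated.
    """
    region_total = len(region_features)
    if region_total == 0:
        raise ValueError("no features in divergent regions")
    genome_total = len(all_features)
    in_regions: dict[str, int] = {}
    totals: dict[str, int] = {}
    has_annotation: dict[str, bool] = {}
    for f in all_features:
        fam = feature_family.get(f.feature_id)
        if fam is None:
            continue
        totals[fam] = totals.get(fam, 0) + 1
        if f.annotation:
            has_annotation[fam] = True
    for f in region_features:
        fam = feature_family.get(f.feature_id)
        if fam is None:
            continue
        in_regions[fam] = in_regions.get(fam, 0) + 1
    out = []
    for fam, k in sorted(in_regions.items()):
        row = EnrichmentRow(
            family_id=fam,
            count_in_regions=k,
            count_total=totals[fam],
            region_feature_total=region_total,
            genome_feature_total=genome_total,
            annotated=has_annotation.get(fam, False),
        )
        if row.count_total >= min_members and row.fold >= min_fold:
            out.append(row)
    out.sort(key=lambda r: -r.fold)
    return out


def plot_profile(profile: GcProfile, segmentation: Segmentation | None = None, path=None):
    """Genome-wide %G+C plot: windows in black, contig boundaries red,
    contig means blue, genome mean green, changepoints dashed green."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 3))
    offset = 0
    for cid in profile.windows.contig_id.unique():
        series = profile.contig_series(cid)
        xs = offset + np.arange(len(series))
        ax.plot(xs, series.gc, color="black", lw=0.5)
        ax.hlines(profile.contig_means[cid], xs[0], xs[-1], color="blue", lw=1)
        if segmentation is not None:
            for cp in segmentation.changepoints.get(cid, []):
                ax.axvline(offset + cp, color="green", ls="--", lw=0.8)
        offset += len(series)
        ax.axvline(offset, color="red", lw=1)
    ax.axhline(profile.genome_mean, color="green", lw=1)
    ax.set_xlabel(f"{profile.config.step_bp} bp steps")
    ax.set_ylabel("%G+C")
    ax.set_title(profile.species_id)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
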