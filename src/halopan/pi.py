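"""Proteome isoelectric-point (pI) profiling.

The net charge of a protein at a given pH is the Henderson-Hasselbalch
sum over its ionizable groups (free termini plus D/E/C/Y acidic and
H/K/R basic side chains); the pI is the unique pH where that monotone
function crosses zero, found by bisection. Whole proteomes are profiled
into 100 fixed bins on [2, 13] — haloarchaeal proteomes show a strongly
acidic major mode near pH 4.5 and a basic minor mode near 10 — and
proteins with pI >= 7.5 are tabulated by annotation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ProteinRecord

HISTOGRAM_RANGE = (2.0, 13.0)
N_BINS = 100
HIGH_PI_THRESHOLD = 7.5


@dataclass(frozen=True)
class PkaTable:
    """pKa constants per ionizable group, with charge sign conventions.

    ``acidic`` groups contribute -1/(1 + 10^(pKa - pH)); ``basic``
    groups +1/(1 + 10^(pH - pKa)). Termini count once per chain, side
    chains once per residue occurrence.
    """

    name: str = "emboss"
    n_terminus: float = 8.6
    c_terminus: float = 3.6
    side_chains_acidic: tuple[tuple[str, float], ...] = (
        ("D", 3.9), ("E", 4.1), ("C", 8.5), ("Y", 10.1),
    )
    side_chains_basic: tuple[tuple[str, float], ...] = (
        ("H", 6.5), ("K", 10.8), ("R", 12.5),
    )

    def __post_init__(self) -> None:
        for v in (
            self.n_terminus, self.c_terminus,
            *[p for _, p in self.side_chains_acidic],
            *[p for _, p in self.side_chains_basic],
        ):
            if not (0 < v < 14):
                raise ValueError("pKa values must lie in (0, 14)")


EMBOSS_PKA = PkaTable()


def net_charge(sequence: str, pH: float, pka: PkaTable | None = None) -> float:
    """Henderson-Hasselbalch net charge of *sequence* at *pH*.

    Residues without a defined pKa (including ambiguity codes B/Z/X)
    contribute no charge.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pka = pka or EMBOSS_PKA
    counts = Counter(sequence.upper())
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
    for aa, pk in pka.side_chains_basic:
        if counts[aa]:
            charge += counts[aa] / (1.0 + 10.0 ** (pH - pk))
    for aa, pk in pka.side_chains_acidic:
        if counts[aa]:
            charge -= counts[aa] / (1.0 + 10.0 ** (pk - pH))
    return charge


def isoelectric_point(
    sequence: str, pka: PkaTable | None = None, tol: float = 1e-4
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    net_charge is strictly decreasing in pH, so the zero is unique;
    the termini guarantee at least one acidic and one basic group.
    """
    pka = pka or EMBOSS_PKA
    lo, hi = 0.0, 14.0
    if net_charge(sequence, lo, pka) <= 0:
        return lo
    if net_charge(sequence, hi, pka) >= 0:
        return hi
    while hi - lo > tol / 2:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class PiProfile:
    """Per-protein pIs, the fixed-bin histogram and the high-pI census."""

    pI: pd.Series                       # index = protein_id
    histogram: np.ndarray               # 100 bins on [2, 13]
    bin_edges: np.ndarray
    high_pi_ids: list[str]
    annotation_tally: pd.DataFrame      # annotation, instances, instances_high_pi
    mean_pi: float
    out_of_range: int = 0
    mode_bins: tuple[int, ...] = field(default_factory=tuple)

    def mode_pis(self) -> list[float]:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return [float(centers[b]) for b in self.mode_bins]


def profile_proteome(
    proteins: list[ProteinRecord], pka: PkaTable | None = None, tol: float = 1e-4
) -> PiProfile:
    """pI profile of one proteome.

    Histogram bin k covers [2 + 0.11k, 2 + 0.11(k+1)), half-open with
    the last bin closed; pIs outside [2, 13] are counted separately and
    excluded from the histogram. The high-pI set uses the inclusive
    pI >= 7.5 rule, and per-annotation tallies are sorted by the number
    of high-pI instances.
    """
    if not proteins:
        raise ValueError("empty proteome")
    pka = pka or EMBOSS_PKA
    pis = pd.Series(
        {p.protein_id: isoelectric_point(p.sequence, pka, tol) for p in proteins}
    )
    lo, hi = HISTOGRAM_RANGE
    edges = np.linspace(lo, hi, N_BINS + 1)
    in_range = pis[(pis >= lo) & (pis <= hi)]
    hist, _ = np.histogram(in_range.to_numpy(), bins=edges)
    out_of_range = len(pis) - len(in_range)

    high = [p.protein_id for p in proteins if pis[p.protein_id] >= HIGH_PI_THRESHOLD]
    tally: dict[str, list[int]] = {}
    for p in proteins:
        ann = p.annotation or "(unannotated)"
        row = tally.setdefault(ann, [0, 0])
        row[0] += 1
        if pis[p.protein_id] >= HIGH_PI_THRESHOLD:
            row[1] += 1
    tally_df = (
        pd.DataFrame(
            [(a, n, h) for a, (n, h) in tally.items()],
            columns=["annotation", "instances", "instances_high_pi"],
        )
        .sort_values("instances_high_pi", ascending=False)
        .reset_index(drop=True)
    )
    mode_bins = tuple(_local_maxima(hist))
    return PiProfile(
        pI=pis,
        histogram=hist,
        bin_edges=edges,
        high_pi_ids=high,
        annotation_tally=tally_df,
        mean_pi=float(pis.mean()),
        out_of_range=out_of_range,
        mode_bins=mode_bins,
    )


def _local_maxima(hist: np.ndarray, smooth: int = 5) -> list[int]:
    """Bin indices of local maxima of the (boxcar-smoothed) histogram,
    largest count first."""
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(hist.astype(float), kernel, mode="same")
    peaks = [
        i
        for i in range(1, len(sm) - 1)
        if sm[i] > 0 and sm[i] >= sm[i - 1] and sm[i] > sm[i + 1]
    ]
    # merge plateau-adjacent peaks, keep order by height
    peaks.sort(key=lambda i: -sm[i])
    kept: list[int] = []
    for p in peaks:
        if all(abs(p - q) > smooth for q in kept):
            kept.append(p)
    return kept


def subunit_pi_labels(
    member_pis: dict[str, list[float]], fraction: float = 0.60
) -> pd.DataFrame:
    """Three-way high/low/variable pI label per family.

    A family is ``high`` when >= *fraction* of its members have
    pI > 7.5, ``low`` when >= *fraction* have pI < 7.5, else
    ``variable``.
    """
    rows = []
    for fam, pis in sorted(member_pis.items()):
        n = len(pis)
        frac_high = sum(p > HIGH_PI_THRESHOLD for p in pis) / n
        frac_low = sum(p < HIGH_PI_THRESHOLD for p in pis) / n
        label = "high" if frac_high >= fraction else ("low" if frac_low >= fraction else "variable")
        rows.append((fam, n, frac_high, label))
    return pd.DataFrame(rows, columns=["family_id", "n_members", "fraction_high_pi", "label"])


def plot_histogram(profile: PiProfile, path=None, title: str = ""):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
    ax.bar(centers, profile.histogram, width=np.diff(profile.bin_edges), color="steelblue")
    ax.set_xlabel("isoelectric point")
    ax.set_ylabel("proteins")
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
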