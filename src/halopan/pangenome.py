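"""Pangenome analysis over a protein FamilySet.

Builds family x species copy-number matrices, rarefaction curves of
discovered family counts (Monte-Carlo plus the closed-form hypergeometric
expectation), the core genome (families present in every genome),
genus-private families, genus marker discovery (universal + exclusive +
single-copy), per-genus descriptive reports, and a conserved-neighborhood
scan that rescues missed gene calls between two anchor families.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .families import FamilySet
from .io import ContigSet, FeatureTable

_STANDARD_TABLE = 11  # archaeal/bacterial translation table
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class PresenceAbsenceMatrix:
    """Copy-number matrix: rows = families, columns = species.

    ``genus_map`` assigns each species (column) to a genus.
    """

    counts: pd.DataFrame
    genus_map: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("copy numbers must be >= 0")

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    def binary(self) -> pd.DataFrame:
        return (self.counts > 0).astype(int)

    def genus_species(self, genus: str) -> list[str]:
        sp = [s for s in self.species if self.genus_map.get(s) == genus]
        if not sp:
            raise KeyError(f"unknown genus {genus!r}")
        return sp


@dataclass
class RarefactionCurve:
    sample_sizes: np.ndarray
    mean_unique_families: np.ndarray
    sd: np.ndarray
    expected: np.ndarray  # closed-form E[U(n)]
    replicates: int
    family_definition: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_genomes": self.sample_sizes,
                "mean_unique_families": self.mean_unique_families,
                "sd": self.sd,
                "expected": self.expected,
            }
        )


@dataclass
class MarkerCriteria:
    genus: str
    require_universal: bool = True
    require_exclusive: bool = True
    require_single_copy: bool = True


def build_matrix(
    families: FamilySet, species_list: list[str], genus_map: dict[str, str] | None = None
) -> PresenceAbsenceMatrix:
    """Copy-number matrix from a FamilySet over *species_list*."""
    for p in families.protein_universe:
        sp = families.species_of.get(p)
        if sp is None or sp not in species_list:
            raise ValueError(f"protein {p!r} maps to no species in species_list")
    fids = sorted(families.families)
    counts = pd.DataFrame(0, index=fids, columns=list(species_list), dtype=int)
    for fid in fids:
        for sp, k in families.copy_numbers(fid).items():
            counts.loc[fid, sp] = k
    return PresenceAbsenceMatrix(counts=counts, genus_map=genus_map or {})


def expected_unique_families(matrix: PresenceAbsenceMatrix, family_definition: str = "mcl_all") -> np.ndarray:
    """Closed-form E[U(n)] for n = 0..N genomes sampled without replacement.

    E[U(n)] = sum_f [1 - C(N - m_f, n) / C(N, n)] where m_f is the
    number of genomes containing family f.
    """
    binary = _definition_view(matrix, family_definition)
    m = binary.sum(axis=1).to_numpy()
    n_genomes = binary.shape[1]
    out = np.zeros(n_genomes + 1)
    for n in range(n_genomes + 1):
        tot = comb(n_genomes, n)
        out[n] = sum(1.0 - comb(n_genomes - mf, n) / tot if n_genomes - mf >= n else 1.0 for mf in m)
    return out


def _definition_view(matrix: PresenceAbsenceMatrix, family_definition: str) -> pd.DataFrame:
    binary = matrix.binary()
    if family_definition in ("mcl_all", "cog"):
        return binary
    if family_definition == "mcl_no_singletons":
        member_counts = matrix.counts.sum(axis=1)
        return binary.loc[member_counts > 1]
    raise ValueError(f"unknown family_definition {family_definition!r}")


def rarefy(
    matrix: PresenceAbsenceMatrix,
    replicates: int = 10_000,
    seed: int = 0,
    family_definition: str = "mcl_all",
    sample_sizes: list[int] | None = None,
) -> RarefactionCurve:
    """Rarefaction curve of unique families vs genomes sampled.

    For each sample size n, *replicates* uniform subsets of n distinct
    genomes are drawn and the number of families present in at least one
    sampled genome averaged. Singleton families (single-member clusters)
    are excluded under ``family_definition="mcl_no_singletons"``. The
    closed-form expectation accompanies the Monte-Carlo curve.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    binary = _definition_view(matrix, family_definition).to_numpy(dtype=bool)
    n_genomes = binary.shape[1]
    sizes = np.array(
        sorted(sample_sizes) if sample_sizes is not None else range(n_genomes + 1)
    )
    if sizes.max(initial=0) > n_genomes:
        raise ValueError("sample size exceeds the number of genomes")
    rng = np.random.default_rng(seed)
    means = np.zeros(len(sizes))
    sds = np.zeros(len(sizes))
    for k, n in enumerate(sizes):
        if n == 0:
            continue
        if n == n_genomes:
            total = binary.any(axis=1).sum()
            means[k], sds[k] = float(total), 0.0
            continue
        vals = np.empty(replicates)
        for r in range(replicates):
            cols = rng.choice(n_genomes, size=n, replace=False)
            vals[r] = binary[:, cols].any(axis=1).sum()
        means[k] = vals.mean()
        sds[k] = vals.std(ddof=1)
    expected_full = expected_unique_families(matrix, family_definition)
    return RarefactionCurve(
        sample_sizes=sizes,
        mean_unique_families=means,
        sd=sds,
        expected=expected_full[sizes],
        replicates=replicates,
        family_definition=family_definition,
        seed=seed,
    )


def core_families(matrix: PresenceAbsenceMatrix) -> set[str]:
    """Families present (copy number > 0) in every genome."""
    binary = matrix.binary()
    return set(binary.index[binary.all(axis=1)])


def genus_specific_families(matrix: PresenceAbsenceMatrix, genus: str) -> set[str]:
    """Families whose every member species belongs to *genus*."""
    inside = matrix.genus_species(genus)
    outside = [s for s in matrix.species if s not in inside]
    binary = matrix.binary()
    has_any = binary[inside].any(axis=1)
    none_outside = ~binary[outside].any(axis=1) if outside else pd.Series(True, index=binary.index)
    return set(binary.index[has_any & none_outside])


def discover_markers(matrix: PresenceAbsenceMatrix, criteria: MarkerCriteria) -> set[str]:
    """Genus marker families: universal within, exclusive to, and
    single-copy in every member of the genus."""
    inside = matrix.genus_species(criteria.genus)
    outside = [s for s in matrix.species if s not in inside]
    counts = matrix.counts
    ok = pd.Series(True, index=counts.index)
    if criteria.require_universal:
        ok &= (counts[inside] > 0).all(axis=1)
    else:
        ok &= (counts[inside] > 0).any(axis=1)
    if criteria.require_exclusive and outside:
        ok &= (counts[outside] == 0).all(axis=1)
    if criteria.require_single_copy:
        ok &= (counts[inside] <= 1).all(axis=1) & (counts[inside] > 0).any(axis=1)
    return set(counts.index[ok])


# ---------------------------------------------------------------------------
# Inter-anchor missed-gene rescue
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).translate(table=_STANDARD_TABLE))


def _ungapped_identity(a: str, b: str) -> float:
    """Percent identity of a position-wise (no-indel) comparison."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return 100.0 * matches / max(len(a), len(b))


def _orfs(seq: str, *, fixed_length: int | None = None):
    """Yield (start, end, strand, frame, nt) for ORFs in all six frames.

    With *fixed_length* set, every contiguous window of that many
    nucleotides is yielded instead (the fixed-window scan mode).
    Coordinates are 0-based half-open on the forward strand.
    """
    L = len(seq)
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        if fixed_length is not None:
            for i in range(0, L - fixed_length + 1):
                nt = s[i:i + fixed_length]
                start, end = (i, i + fixed_length) if strand == "+" else (L - i - fixed_length, L - i)
                yield start, end, strand, i % 3, nt
            continue
        for frame in range(3):
            i = frame
            while i + 3 <= L:
                codon = s[i:i + 3]
                if codon in START_CODONS:
                    j = i + 3
                    while j + 3 <= L:
                        if s[j:j + 3] in STOP_CODONS:
                            nt = s[i:j + 3]
                            start, end = (i, j + 3) if strand == "+" else (L - j - 3, L - i)
                            yield start, end, strand, frame, nt
                            break
                        j += 3
                i += 3


def rescue_missed_genes(
    anchor_a: str,
    anchor_b: str,
    target: str,
    families: FamilySet,
    genomes: dict[str, ContigSet],
    features: dict[str, FeatureTable],
    family_sequences: dict[str, str],
    feature_family: dict[str, str],
    max_span_bp: int = 5000,
    length_tolerance: float = 0.2,
    min_identity: float = 30.0,
    fixed_length: int | None = None,
) -> list[dict]:
    """Scan conserved anchor_a .. anchor_b neighborhoods for an uncalled
    copy of the *target* family.

    For each species where both anchors are called within *max_span_bp*
    on one contig and the target family has no call between them, the
    inter-anchor sequence is scanned in all six frames for ORFs whose
    nucleotide length is within +-*length_tolerance* of the target
    family's median member length; candidates whose ungapped protein
    identity to any family member is >= *min_identity* are reported,
    best first. ``fixed_length`` switches to the fixed-window scan
    (e.g. 117 nt) instead of the ORF definition.

    *family_sequences* maps protein_id -> amino-acid sequence for the
    target family members; *feature_family* maps feature_id -> family_id.
    """
    target_members = families.families[target]
    member_seqs = [family_sequences[p] for p in sorted(target_members) if p in family_sequences]
    if not member_seqs:
        raise ValueError(f"no sequences supplied for target family {target!r}")
    median_nt = 3 * (int(np.median([len(s) for s in member_seqs])) + 1)

    candidates: list[dict] = []
    for sp, ftable in features.items():
        placed: dict[str, list] = {}
        for f in ftable.features:
            fam = feature_family.get(f.feature_id)
            if fam in (anchor_a, anchor_b, target):
                placed.setdefault(fam, []).append(f)
        if anchor_a not in placed or anchor_b not in placed:
            continue
        fa, fb = placed[anchor_a][0], placed[anchor_b][0]
        if fa.contig_id != fb.contig_id:
            continue  # anchors on different contigs: species skipped
        left, right = (fa, fb) if fa.start <= fb.start else (fb, fa)
        gap_start, gap_end = left.end, right.start
        if right.start - left.end > max_span_bp or gap_end <= gap_start:
            continue
        has_target_between = any(
            f.contig_id == fa.contig_id and gap_start <= f.start and f.end <= gap_end
            for f in placed.get(target, [])
        )
        if has_target_between:
            continue
        contig_seq = genomes[sp].sequence(fa.contig_id)
        gap_seq = contig_seq[gap_start:gap_end]
        lo = median_nt * (1 - length_tolerance)
        hi = median_nt * (1 + length_tolerance)
        for start, end, strand, frame, nt in _orfs(gap_seq, fixed_length=fixed_length):
            if not (lo <= len(nt) <= hi):
                continue
            prot = _translate(nt).rstrip("*")
            best = max(_ungapped_identity(prot, ms) for ms in member_seqs)
            if best >= min_identity:
                candidates.append(
                    {
                        "species": sp,
                        "contig": fa.contig_id,
                        "start": gap_start + start,
                        "end": gap_start + end,
                        "strand": strand,
                        "frame": frame,
                        "protein": prot,
                        "identity": best,
                    }
                )
    candidates.sort(key=lambda c: -c["identity"])
    return candidates


def genus_report(
    matrix: PresenceAbsenceMatrix, genome_stats: pd.DataFrame
) -> pd.DataFrame:
    """Per-genus quartiles (25th/50th/75th, linear interpolation) of
    per-genome statistics (rows of *genome_stats* = species)."""
    stats = genome_stats.copy()
    stats["genus"] = [matrix.genus_map.get(s, "?") for s in stats.index]
    rows = []
    for genus, grp in stats.groupby("genus"):
        for col in genome_stats.columns:
            q25, q50, q75 = np.percentile(grp[col].to_numpy(float), [25, 50, 75])
            rows.append((genus, col, len(grp), q25, q50, q75))
    return pd.DataFrame(
        rows, columns=["genus", "statistic", "n_genomes", "q25", "median", "q75"]
    )
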