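"""Readers, writers and the shared genomic data model.

Everything downstream (family clustering, pangenome analysis, G+C
landscapes, pI profiling) consumes the containers defined here:
nucleotide :class:`ContigSet`, protein :class:`ProteinRecord` lists,
tabular :class:`SimilarityEdge` lists in the standard 12-column search
dialect, and per-contig :class:`FeatureTable` annotations.

Coordinates are 0-based half-open internally; GFF3's 1-based closed
convention is converted at the file boundary.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC nucleotide alphabet; every code other than A/C/G/T counts as
# ambiguous wherever ambiguity matters (conservative superset of N).
NUCLEOTIDE_ALPHABET = set("ACGTNRYSWKMBDHV")
AMBIGUOUS_NUCLEOTIDES = NUCLEOTIDE_ALPHABET - set("ACGT")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXUO*")


class DuplicateIdError(ValueError):
    """Raised when a FASTA file contains two records with the same ID."""


@dataclass
class ContigSet:
    """A genome assembly: ordered contigs for one species."""

    species_id: str
    contigs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, seq in self.contigs:
            if cid in seen:
                raise DuplicateIdError(f"duplicate contig id {cid!r}")
            seen.add(cid)
            if not seq:
                raise ValueError(f"contig {cid!r} has an empty sequence")
            bad = set(seq.upper()) - NUCLEOTIDE_ALPHABET
            if bad:
                raise ValueError(
                    f"contig {cid!r} contains non-nucleotide characters {sorted(bad)}"
                )

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def total_bp(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass(frozen=True)
class ProteinRecord:
    """One called protein: id, source species, sequence and annotation."""

    protein_id: str
    species_id: str
    sequence: str
    annotation: str = ""

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass
class SimilarityEdge:
    """One row of an all-vs-all similarity search (12-column dialect).

    ``qcov``/``scov`` are the fractions of the query/subject length
    covered by the (single best) aligned span, in [0, 1].
    """

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    pct_identity: float
    qcov: float
    scov: float
    qlen: int
    slen: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (0.0 <= self.qcov <= 1.0 and 0.0 <= self.scov <= 1.0):
            raise ValueError("qcov/scov must lie in [0, 1]")

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id


@dataclass(frozen=True)
class Feature:
    """A genomic feature in 0-based half-open coordinates."""

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    annotation: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"feature {self.feature_id!r}: need 0 <= start < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.feature_id!r}: strand must be + or -")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class FeatureTable:
    """Per-contig feature lists for one species."""

    species_id: str
    features: list[Feature] = field(default_factory=list)

    def by_contig(self, contig_id: str) -> list[Feature]:
        return [f for f in self.features if f.contig_id == contig_id]

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class ContaminationRules:
    """Thresholds for the assembly contamination screen.

    A similarity hit is significant when its E-value is at most
    ``significant_evalue_max``. Contigs with significant hits covering
    at least ``contig_coverage_min`` of their length, and contigs no
    longer than ``short_contig_max_bp`` with any significant hit, are
    removed. Longer contigs with only small-portion hits are removed
    only when they carry no native features (or only features annotated
    as belonging to a contaminant taxon); otherwise they are flagged.
    """

    significant_evalue_max: float = 1e-20
    contig_coverage_min: float = 0.80
    short_contig_max_bp: int = 1000
    contaminant_taxa: tuple[str, ...] = ("Escherichia coli", "E. coli", "pWH1891")

    def __post_init__(self) -> None:
        for name in ("significant_evalue_max", "contig_coverage_min", "short_contig_max_bp"):
            v = getattr(self, name)
            if not (v > 0 and v == v and v != float("inf")):
                raise ValueError(f"{name} must be finite and positive")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, *, kind: str = "auto", species_id: str | None = None):
    """Read a FASTA file into a :class:`ContigSet` or ``list[ProteinRecord]``.

    Parameters
    ----------
    kind:
        ``"nucleotide"``, ``"protein"`` or ``"auto"`` (guess from residue
        composition of the first record).
    species_id:
        Species the records belong to; defaults to the file stem.

    Sequences are uppercased and line wrapping is normalized. Duplicate
    IDs and empty records are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if species_id is None:
        import os

        species_id = os.path.splitext(os.path.basename(str(path)))[0]
    seen: set[str] = set()
    seqs: list[tuple[str, str]] = []
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        seqs.append((rec.id, seq))
    if not seqs:
        raise ValueError(f"no records in {path}")
    if kind == "auto":
        sample = seqs[0][1]
        nuc = sum(c in "ACGTN" for c in sample)
        kind = "nucleotide" if nuc / len(sample) > 0.9 else "protein"
    if kind == "nucleotide":
        return ContigSet(species_id=species_id, contigs=seqs)
    if kind == "protein":
        out = []
        for rec, (rid, seq) in zip(records, seqs):
            desc = rec.description
            annotation = desc[len(rec.id):].strip() if desc.startswith(rec.id) else desc
            out.append(ProteinRecord(rid, species_id, seq, annotation))
        return out
    raise ValueError(f"unknown kind {kind!r}")


def write_fasta(records, path, *, width: int = 60) -> None:
    """Write a ContigSet or iterable of ProteinRecord to FASTA."""
    seqrecords = []
    if isinstance(records, ContigSet):
        for cid, seq in records.contigs:
            seqrecords.append(SeqRecord(Seq(seq), id=cid, description=""))
    else:
        for p in records:
            seqrecords.append(
                SeqRecord(Seq(p.sequence), id=p.protein_id, description=p.annotation)
            )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# Similarity tables (12-column tabular dialect, optional qlen/slen columns)
# ---------------------------------------------------------------------------

_TAB12 = [
    "query_id", "subject_id", "pct_identity", "aln_len", "mismatches",
    "gap_opens", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_similarity_table(path, *, length_map: dict[str, int] | None = None):
    """Read a 12(+2)-column tabular similarity file into SimilarityEdge list.

    Coverage on each sequence is computed from the aligned span divided
    by the full sequence length. Sequence lengths come from the optional
    ``qlen``/``slen`` columns 13-14 or, failing that, from *length_map*;
    with neither, a hard error instructs the caller to pass a length map.
    Rows with unparsable numerics are rejected with their line numbers.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] not in (12, 14):
        raise ValueError(
            f"{path}: expected 12 or 14 tab-separated columns, got {df.shape[1]}"
        )
    has_lens = df.shape[1] == 14
    cols = _TAB12 + (["qlen", "slen"] if has_lens else [])
    df.columns = cols
    numeric = [c for c in cols if c not in ("query_id", "subject_id")]

    def _float_or_nan(v):
        # Python's float() is correctly rounded; pandas' fast parser is not
        try:
            return float(v)
        except (TypeError, ValueError):
            return float("nan")

    converted = df[numeric].apply(lambda col: col.map(_float_or_nan))
    bad = converted.isna().any(axis=1)
    if bad.any():
        lines = [i + 1 for i in df.index[bad]]
        raise ValueError(f"{path}: unparsable numeric fields on line(s) {lines}")
    df[numeric] = converted

    edges: list[SimilarityEdge] = []
    n_self = 0
    for row in df.itertuples(index=False):
        q, s = row.query_id, row.subject_id
        if has_lens:
            qlen, slen = int(row.qlen), int(row.slen)
        else:
            if length_map is None or q not in length_map or s not in length_map:
                raise ValueError(
                    f"{path}: no qlen/slen columns and no sequence length for "
                    f"{q!r}/{s!r}; pass length_map={{id: length}}"
                )
            qlen, slen = length_map[q], length_map[s]
        qspan = abs(int(row.qend) - int(row.qstart)) + 1
        sspan = abs(int(row.send) - int(row.sstart)) + 1
        edge = SimilarityEdge(
            query_id=q, subject_id=s,
            evalue=float(row.evalue), bitscore=float(row.bitscore),
            pct_identity=float(row.pct_identity),
            qcov=min(1.0, qspan / qlen), scov=min(1.0, sspan / slen),
            qlen=qlen, slen=slen,
        )
        n_self += edge.is_self
        edges.append(edge)
    if n_self:
        warnings.warn(f"{path}: {n_self} self-edges present", stacklevel=2)
    return edges


def write_similarity_table(edges, path) -> None:
    """Write edges in the 14-column dialect read back by read_similarity_table.

    Floats are printed with Python's shortest round-trippable repr so a
    write/read cycle preserves the edge multiset exactly.
    """
    with open(path, "w") as fh:
        for e in edges:
            qspan = max(1, round(e.qcov * e.qlen))
            sspan = max(1, round(e.scov * e.slen))
            row = (e.query_id, e.subject_id, repr(e.pct_identity), qspan, 0, 0,
                   1, qspan, 1, sspan, repr(e.evalue), repr(e.bitscore),
                   e.qlen, e.slen)
            fh.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path, species_id: str | None = None) -> FeatureTable:
    """Read a GFF3 file, converting 1-based closed to 0-based half-open."""
    if species_id is None:
        import os

        species_id = os.path.splitext(os.path.basename(str(path)))[0]
    feats: list[Feature] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{i}: expected 9 GFF3 columns")
            seqid, _src, _type, start, end, _score, strand, _phase, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            fid = attr.get("ID", f"{seqid}:{start}-{end}")
            feats.append(
                Feature(
                    feature_id=fid, contig_id=seqid,
                    start=int(start) - 1, end=int(end),
                    strand=strand if strand in "+-" else "+",
                    annotation=attr.get("product", attr.get("Name", "")),
                )
            )
    return FeatureTable(species_id=species_id, features=feats)


def write_gff3(table: FeatureTable, path, *, source: str = "halopan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in table.features:
            attrs = f"ID={f.feature_id}"
            if f.annotation:
                attrs += f";product={f.annotation}"
            fh.write(
                "\t".join(
                    [f.contig_id, source, "CDS", str(f.start + 1), str(f.end),
                     ".", f.strand, "0", attrs]
                ) + "\n"
            )


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a TSV matrix (rows = families/queries, columns = species)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Contamination filter
# ---------------------------------------------------------------------------

def filter_contamination(
    contigs: ContigSet,
    hits: list[SimilarityEdge],
    features: FeatureTable | None = None,
    rules: ContaminationRules | None = None,
):
    """Screen assembled contigs against a contaminant database.

    *hits* are similarity edges whose ``query_id`` is a contig of
    *contigs* and whose coverage fields refer to the contig (query)
    side. Only hits at or below ``rules.significant_evalue_max`` count.

    Returns ``(kept: ContigSet, removed: list[(contig_id, reason)],
    flagged: list[contig_id], report: dict)``. Reasons are
    ``"coverage>=threshold"``, ``"short_contig_any_hit"`` and
    ``"long_contig_no_native_features"``. Long contigs with only a
    small-portion significant match survive when they carry at least
    one feature not annotated as a contaminant taxon, but are flagged
    for review.
    """
    rules = rules or ContaminationRules()
    known = set(contigs.contig_ids)
    sig: dict[str, float] = {}
    for h in hits:
        if h.query_id not in known:
            warnings.warn(
                f"contamination hit to unknown contig {h.query_id!r}; skipped",
                stacklevel=2,
            )
            continue
        if h.evalue <= rules.significant_evalue_max:
            sig[h.query_id] = max(sig.get(h.query_id, 0.0), h.qcov)

    def native_feature_count(cid: str) -> int:
        if features is None:
            return 0
        n = 0
        for f in features.by_contig(cid):
            if not any(t.lower() in f.annotation.lower() for t in rules.contaminant_taxa):
                n += 1
        return n

    kept: list[tuple[str, str]] = []
    removed: list[tuple[str, str]] = []
    flagged: list[str] = []
    removed_bp = 0
    for cid, seq in contigs.contigs:
        if cid not in sig:
            kept.append((cid, seq))
            continue
        cov = sig[cid]
        if cov >= rules.contig_coverage_min:
            removed.append((cid, "coverage>=threshold"))
            removed_bp += len(seq)
        elif len(seq) <= rules.short_contig_max_bp:
            removed.append((cid, "short_contig_any_hit"))
            removed_bp += len(seq)
        elif native_feature_count(cid) == 0:
            removed.append((cid, "long_contig_no_native_features"))
            removed_bp += len(seq)
        else:
            flagged.append(cid)
            kept.append((cid, seq))
    report = {
        "n_removed": len(removed),
        "bp_removed": removed_bp,
        "n_flagged": len(flagged),
        "n_kept": len(kept),
    }
    kept_set = ContigSet(species_id=contigs.species_id, contigs=kept)
    return kept_set, removed, flagged, report
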