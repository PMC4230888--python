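"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and a seed, and
returns the generated dataset together with a :class:`TruthBundle`
recording all planted structure (family partition, core set, planted
G+C segments, transfer scenarios, deleted-gene coordinates, proteome
mode fractions), so every pipeline stage can be scored against known
ground truth without re-reading generator internals.

The generators emulate the salient statistical features of a
haloarchaeal comparative-genomics dataset: a pangenome with core and
accessory protein families and occasional paralogs, high-G+C contigs
with A+T-shifted (or G+C-shifted) islands, proteomes with a bimodal
isoelectric-point composition dominated by an acidic mode, and gene
trees under known bacteria-to-haloarchaea transfer scenarios. Sequence
evolution is i.i.d. point mutation without indels, which keeps pairwise
identity analytically predictable for threshold-based recruitment
tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .families import FamilySet
from .io import ContigSet, Feature, FeatureTable, ProteinRecord, SimilarityEdge
from .pangenome import PresenceAbsenceMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# one representative codon per amino acid (reverse translation)
_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGC",
    "S": "TCG", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}


@dataclass
class TruthBundle:
    scenario: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=default)


def _random_protein(rng, length: int, probs=None) -> str:
    aas = np.array(list(AMINO_ACIDS))
    return "".join(rng.choice(aas, size=length, p=probs))


def _mutate(rng, seq: str, rate: float, alphabet: str = AMINO_ACIDS) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [c for c in alphabet if c != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return 100.0 * sum(x == y for x, y in zip(a, b)) / max(len(a), len(b), 1)


# ---------------------------------------------------------------------------
# Pangenome with planted family structure
# ---------------------------------------------------------------------------

def gen_pangenome(
    n_genomes: int = 12,
    n_genera: int = 4,
    n_core: int = 25,
    n_accessory: int = 60,
    presence_prob: float = 0.4,
    paralog_prob: float = 0.05,
    length_range: tuple[int, int] = (80, 400),
    mutation_rate: float = 0.05,
    noise_edges: int = 0,
    n_genus_private: int = 0,
    seed: int = 0,
):
    """Synthetic pangenome: proteomes, planted families and edge table.

    Every family descends from one ancestral random sequence; members
    are point-mutated copies. Core families appear in all genomes,
    accessory families in each genome independently with
    *presence_prob*, and genus-private families only within one genus.
    The similarity table carries all within-family pairs (passing the
    clustering thresholds) and, optionally, *noise_edges* random
    between-family edges with sub-threshold E-values.

    Returns ``(proteomes, families, matrix, edges, truth)``.
    """
    for p in (presence_prob, paralog_prob, mutation_rate):
        if not (0 <= p <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    species = [f"sp{g:02d}_{i:02d}" for g in range(n_genera) for i in range(
        n_genomes // n_genera + (1 if g < n_genomes % n_genera else 0))]
    species = species[:n_genomes]
    genus_map = {sp: f"genus{sp[2:4]}" for sp in species}
    genera = sorted(set(genus_map.values()))

    fam_specs = []  # (family_id, kind, genus or None)
    for k in range(n_core):
        fam_specs.append((f"core{k:04d}", "core", None))
    for k in range(n_accessory):
        fam_specs.append((f"acc{k:04d}", "accessory", None))
    for k in range(n_genus_private):
        fam_specs.append((f"priv{k:04d}", "private", genera[k % len(genera)]))

    proteomes: dict[str, list[ProteinRecord]] = {sp: [] for sp in species}
    families: dict[str, set[str]] = {}
    species_of: dict[str, str] = {}
    sequences: dict[str, str] = {}
    counts = np.zeros((len(fam_specs), len(species)), dtype=int)

    for fi, (fid, kind, genus) in enumerate(fam_specs):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        ancestral = _random_protein(rng, L)
        for si, sp in enumerate(species):
            if kind == "core":
                present = True
            elif kind == "accessory":
                present = rng.random() < presence_prob
            else:
                present = genus_map[sp] == genus
            if not present:
                continue
            ncopies = 2 if rng.random() < paralog_prob else 1
            for c in range(ncopies):
                pid = f"{sp}|{fid}|{c}"
                seq = _mutate(rng, ancestral, mutation_rate)
                proteomes[sp].append(ProteinRecord(pid, sp, seq, annotation=fid))
                families.setdefault(fid, set()).add(pid)
                species_of[pid] = sp
                sequences[pid] = seq
                counts[fi, si] += 1
        if fid not in families:  # accessory family that landed nowhere
            counts[fi, :] = 0

    planted = {fid: m for fid, m in families.items()}
    famset = FamilySet(families=planted, species_of=species_of)
    import pandas as pd

    present_fids = [fs[0] for fs in fam_specs if fs[0] in families]
    count_df = pd.DataFrame(
        counts[[i for i, fs in enumerate(fam_specs) if fs[0] in families]],
        index=present_fids, columns=species,
    )
    matrix = PresenceAbsenceMatrix(counts=count_df, genus_map=genus_map)

    edges: list[SimilarityEdge] = []
    for fid, members in families.items():
        mem = sorted(members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                a, b = mem[i], mem[j]
                edges.append(
                    SimilarityEdge(
                        a, b, evalue=1e-50, bitscore=200.0,
                        pct_identity=_identity(sequences[a], sequences[b]),
                        qcov=1.0, scov=1.0,
                        qlen=len(sequences[a]), slen=len(sequences[b]),
                    )
                )
    all_pids = sorted(species_of)
    fam_of = famset.family_of()
    added = 0
    while added < noise_edges and len(all_pids) > 1:
        a, b = rng.choice(all_pids, size=2, replace=False)
        if fam_of[a] == fam_of[b]:
            continue
        edges.append(
            SimilarityEdge(
                a, b, evalue=1e-3, bitscore=30.0,
                pct_identity=20.0, qcov=0.5, scov=0.5,
                qlen=len(sequences[a]), slen=len(sequences[b]),
            )
        )
        added += 1

    truth = TruthBundle(
        scenario="pangenome",
        seed=seed,
        params=dict(
            n_genomes=n_genomes, n_genera=n_genera, n_core=n_core,
            n_accessory=n_accessory, presence_prob=presence_prob,
            paralog_prob=paralog_prob, mutation_rate=mutation_rate,
            noise_edges=noise_edges, n_genus_private=n_genus_private,
        ),
        truth=dict(
            core_families=sorted(f for f, k, _ in fam_specs if k == "core"),
            genus_private={
                g: sorted(f for f, k, gg in fam_specs if k == "private" and gg == g and f in families)
                for g in genera
            },
            genus_map=genus_map,
            n_families=len(families),
        ),
    )
    return proteomes, famset, matrix, edges, truth


def gen_block_edges(
    n: int = 60,
    n_blocks: int = 3,
    p_within: float = 0.9,
    p_between: float = 0.02,
    seed: int = 0,
):
    """Planted-partition similarity graph for clustering benchmarks.

    Nodes split evenly into *n_blocks* blocks; each within-block pair
    gets an edge with probability *p_within* (strong weight), each
    between-block pair with probability *p_between* (weak weight).
    Returns (edges, truth_labels) with truth_labels[node_id] = block.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:03d}" for i in range(n)]
    labels = {nodes[i]: i * n_blocks // n for i in range(n)}
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            same = labels[nodes[i]] == labels[nodes[j]]
            p = p_within if same else p_between
            if rng.random() < p:
                ev = 1e-40 if same else 1e-12
                edges.append(
                    SimilarityEdge(
                        nodes[i], nodes[j], evalue=ev,
                        bitscore=150.0 if same else 40.0,
                        pct_identity=60.0 if same else 25.0,
                        qcov=1.0, scov=1.0, qlen=300, slen=300,
                    )
                )
    return edges, labels


# ---------------------------------------------------------------------------
# Genomes with planted G+C segments
# ---------------------------------------------------------------------------

def gen_genome(
    contig_lengths: list[int] = (50_000,),
    background_gc: float = 0.62,
    planted_segments: list[tuple[int, int, int, float]] = (),
    n_fraction: float = 0.0,
    seed: int = 0,
    species_id: str = "synthetic",
):
    """Contigs with i.i.d. bases at a local target G+C.

    *planted_segments* entries are (contig_index, start_bp, length_bp,
    gc) intervals where the base-composition target switches to *gc*.
    Ambiguous N bases are sprinkled uniformly at *n_fraction*.
    Returns (ContigSet, TruthBundle).
    """
    rng = np.random.default_rng(seed)
    contigs = []
    for ci, L in enumerate(contig_lengths):
        gc_target = np.full(L, background_gc)
        for (tci, start, length, gc) in planted_segments:
            if tci == ci:
                gc_target[start:start + length] = gc
        r_gc = rng.random(L)
        r_which = rng.integers(0, 2, size=L)
        bases = np.where(
            r_gc < gc_target,
            np.where(r_which == 0, ord("G"), ord("C")),
            np.where(r_which == 0, ord("A"), ord("T")),
        ).astype(np.uint8)
        if n_fraction > 0:
            mask = rng.random(L) < n_fraction
            bases[mask] = ord("N")
        contigs.append((f"contig{ci:02d}", bases.tobytes().decode()))
    truth = TruthBundle(
        scenario="gc_genome",
        seed=seed,
        params=dict(
            contig_lengths=list(contig_lengths), background_gc=background_gc,
            n_fraction=n_fraction,
        ),
        truth=dict(planted_segments=[list(s) for s in planted_segments]),
    )
    return ContigSet(species_id=species_id, contigs=contigs), truth


# ---------------------------------------------------------------------------
# Bimodal proteomes
# ---------------------------------------------------------------------------

ACIDIC_COMPOSITION = {"D": 0.12, "E": 0.12, "K": 0.02, "R": 0.02, "H": 0.02}
BASIC_COMPOSITION = {"K": 0.12, "R": 0.12, "D": 0.02, "E": 0.02, "H": 0.03}


def _composition_probs(overrides: dict[str, float]) -> np.ndarray:
    rest = 1.0 - sum(overrides.values())
    others = [a for a in AMINO_ACIDS if a not in overrides]
    probs = np.array(
        [overrides.get(a, rest / len(others)) for a in AMINO_ACIDS]
    )
    return probs / probs.sum()


def gen_proteome(
    n: int = 1000,
    acidic_fraction: float = 0.8,
    acidic_composition: dict[str, float] | None = None,
    basic_composition: dict[str, float] | None = None,
    length_range: tuple[int, int] = (50, 500),
    seed: int = 0,
    species_id: str = "synthetic",
):
    """Proteome with a bimodal pI composition.

    A fraction *acidic_fraction* of proteins is drawn from a D/E-
    enriched composition (acidic mode, the haloarchaeal majority); the
    remainder from a K/R-enriched one (basic minority mode). Returns
    (records, TruthBundle) where the truth records each protein's mode.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p_acid = _composition_probs(acidic_composition or ACIDIC_COMPOSITION)
    p_base = _composition_probs(basic_composition or BASIC_COMPOSITION)
    records, modes = [], {}
    for i in range(n):
        acidic = rng.random() < acidic_fraction
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _random_protein(rng, L, p_acid if acidic else p_base)
        pid = f"{species_id}|p{i:05d}"
        records.append(
            ProteinRecord(pid, species_id, seq, annotation="acidic" if acidic else "basic")
        )
        modes[pid] = "acidic" if acidic else "basic"
    truth = TruthBundle(
        scenario="bimodal_proteome",
        seed=seed,
        params=dict(n=n, acidic_fraction=acidic_fraction, length_range=list(length_range)),
        truth=dict(modes=modes),
    )
    return records, truth


# ---------------------------------------------------------------------------
# Gene trees under known transfer scenarios
# ---------------------------------------------------------------------------

def _random_clade(rng, labels: list[str]) -> str:
    """Random binary newick subtree over *labels*."""
    items = [str(x) for x in labels]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b})")
    return items[0]


def _apply_nni(newick: str, n_moves: int, rng) -> str:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    for _ in range(n_moves):
        internal = [
            e for e in tree.preorder_edge_iter()
            if e.head_node is not None and e.tail_node is not None
            and not e.head_node.is_leaf() and e.tail_node.parent_node is not None
        ]
        if not internal:
            break
        edge = internal[rng.integers(len(internal))]
        child, parent = edge.head_node, edge.tail_node
        siblings = [c for c in parent.child_nodes() if c is not child]
        grandkids = child.child_nodes()
        if not siblings or len(grandkids) < 2:
            continue
        s = siblings[rng.integers(len(siblings))]
        g = grandkids[rng.integers(len(grandkids))]
        parent.remove_child(s)
        child.remove_child(g)
        parent.add_child(g)
        child.add_child(s)
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def gen_gene_trees(
    scenario: str,
    n_trees: int = 10,
    n_H: int = 6,
    n_A: int = 4,
    n_E: int = 6,
    nni_noise: int = 0,
    seed: int = 0,
):
    """Labeled gene trees under a known transfer scenario.

    ``basal_transfer`` attaches the H tips as one clade inside the
    bacterial subtree (truth: basal_import); ``multiple_transfer``
    splits the H tips across two bacterial attachment points;
    ``no_transfer`` nests the H clade among the archaea; ``scattered``
    pairs each H tip with its own bacterial sister (truth for all
    three: non_monophyly). *nni_noise* random nearest-neighbor
    interchanges are applied after construction; truth verdicts are
    recorded before noise. Returns list of (newick, truth_verdict).
    """
    rng = np.random.default_rng(seed)
    H = [f"H{i}" for i in range(1, n_H + 1)]
    A = [f"A{i}" for i in range(1, n_A + 1)]
    E = [f"E{i}" for i in range(1, n_E + 1)]
    out = []
    for _ in range(n_trees):
        if scenario == "basal_transfer":
            if n_E < 3 or len(E[3:]) + n_A < 2:
                raise ValueError("basal_transfer needs n_E >= 3 and n_E + n_A >= 5")
            h = _random_clade(rng, H)
            e_sister = _random_clade(rng, E[:2])
            rest = _random_clade(rng, E[3:] + A)
            nwk = f"(({h},{e_sister}),({E[2]},{rest}));"
            verdict = "basal_import"
        elif scenario == "multiple_transfer":
            if n_H < 2 or n_E < 2:
                raise ValueError("multiple_transfer needs n_H >= 2 and n_E >= 2")
            k = max(1, n_H // 2)
            h1 = _random_clade(rng, H[:k])
            h2 = _random_clade(rng, H[k:])
            e1 = _random_clade(rng, E[: n_E // 2])
            e2 = _random_clade(rng, E[n_E // 2:])
            rest = _random_clade(rng, A)
            nwk = f"(({h1},{e1}),(({h2},{e2}),{rest}));"
            verdict = "non_monophyly"
        elif scenario == "no_transfer":
            if n_A < 3 or n_E < 1:
                raise ValueError("no_transfer needs n_A >= 3 and n_E >= 1")
            h = _random_clade(rng, H)
            a_sister = _random_clade(rng, A[:2])
            rest = _random_clade(rng, A[3:] + E) if (len(A) > 3 or E) else _random_clade(rng, E)
            nwk = f"(({h},{a_sister}),({A[2]},{rest}));"
            verdict = "non_monophyly"
        elif scenario == "scattered":
            if n_E < n_H or n_H < 2:
                raise ValueError("scattered needs n_E >= n_H >= 2")
            cherries = [f"({h},{e})" for h, e in zip(H, E)]
            rest = E[n_H:] + A
            nwk = _random_clade(rng, cherries + rest) + ";"
            verdict = "non_monophyly"
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        if nni_noise > 0:
            nwk = _apply_nni(nwk, nni_noise, rng)
        out.append((nwk, verdict))
    return out


# ---------------------------------------------------------------------------
# Missed-gene neighborhoods
# ---------------------------------------------------------------------------

def _reverse_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


def gen_missed_gene_case(
    n_species: int = 6,
    deleted_species: tuple[int, ...] = (0,),
    target_length_aa: int = 39,
    anchor_length_aa: int = 100,
    spacer_bp: int = 150,
    flank_bp: int = 500,
    mutation_rate: float = 0.0,
    seed: int = 0,
):
    """Conserved anchorA-target-anchorB neighborhoods across species.

    Every species carries the three-gene synteny in sequence; in the
    *deleted_species* the target is removed from the feature table but
    left intact in the genome (a missed gene call). *mutation_rate*
    point-mutates the target protein per species (realized identities
    recorded in the truth). Returns (genomes, features, families,
    family_sequences, feature_family, truth).
    """
    rng = np.random.default_rng(seed)
    anchor_a_prot = "M" + _random_protein(rng, anchor_length_aa - 1)
    anchor_b_prot = "M" + _random_protein(rng, anchor_length_aa - 1)
    target_prot = "M" + _random_protein(rng, target_length_aa - 1)

    genomes: dict[str, ContigSet] = {}
    features: dict[str, FeatureTable] = {}
    fam: dict[str, set[str]] = {"famA": set(), "famB": set(), "famT": set()}
    species_of: dict[str, str] = {}
    family_sequences: dict[str, str] = {}
    feature_family: dict[str, str] = {}
    coords: dict[str, dict] = {}
    identities: dict[str, float] = {}
    all_targets: dict[str, str] = {}

    for si in range(n_species):
        sp = f"sp{si:02d}"
        tgt = _mutate(rng, target_prot, mutation_rate) if mutation_rate > 0 else target_prot
        tgt = "M" + tgt[1:]  # keep the start residue
        identities[sp] = _identity(tgt, target_prot)
        all_targets[sp] = tgt
        nt_a = _reverse_translate(anchor_a_prot)
        nt_t = _reverse_translate(tgt)
        nt_b = _reverse_translate(anchor_b_prot)

        def _spacer(n):
            # spacers free of ATG/GTG/TTG start codons so the only
            # qualifying ORF between the anchors is the planted gene
            return "".join(rng.choice(list("AC"), size=n))

        parts = [_spacer(flank_bp), nt_a, _spacer(spacer_bp), nt_t,
                 _spacer(spacer_bp), nt_b, _spacer(flank_bp)]
        offsets = np.cumsum([0] + [len(p) for p in parts])
        seq = "".join(parts)
        genomes[sp] = ContigSet(species_id=sp, contigs=[("c0", seq)])

        feats = []
        ids = {}
        for name, prot, k in (("A", anchor_a_prot, 1), ("T", tgt, 3), ("B", anchor_b_prot, 5)):
            fid_feat = f"{sp}|{name}"
            ids[name] = fid_feat
            feats.append(
                Feature(fid_feat, "c0", int(offsets[k]), int(offsets[k + 1]), "+", name)
            )
        deleted = si in deleted_species
        kept_feats = [f for f in feats if not (deleted and f.feature_id == ids["T"])]
        features[sp] = FeatureTable(species_id=sp, features=kept_feats)

        fam["famA"].add(ids["A"])
        fam["famB"].add(ids["B"])
        species_of[ids["A"]] = species_of[ids["B"]] = sp
        feature_family[ids["A"]] = "famA"
        feature_family[ids["B"]] = "famB"
        if not deleted:
            fam["famT"].add(ids["T"])
            species_of[ids["T"]] = sp
            family_sequences[ids["T"]] = tgt
            feature_family[ids["T"]] = "famT"
        coords[sp] = {"target_start": int(offsets[3]), "target_end": int(offsets[4]),
                      "deleted": deleted}

    families = FamilySet(families=fam, species_of=species_of)
    # a rescue scan compares candidates against the surviving family
    # members, so record the best attainable identity per deleted species
    survivors = [all_targets[f"sp{si:02d}"] for si in range(n_species)
                 if si not in deleted_species]
    best_member_identity = {
        f"sp{si:02d}": max(_identity(all_targets[f"sp{si:02d}"], s) for s in survivors)
        for si in deleted_species
    }
    truth = TruthBundle(
        scenario="missed_gene",
        seed=seed,
        params=dict(
            n_species=n_species, deleted_species=list(deleted_species),
            target_length_aa=target_length_aa, mutation_rate=mutation_rate,
        ),
        truth=dict(coordinates=coords, identities=identities,
                   best_member_identity=best_member_identity),
    )
    return genomes, features, families, family_sequences, feature_family, truth
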