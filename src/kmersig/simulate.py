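"""Synthetic archaeal-like genome sets with controlled compositional structure.

The generator emulates the structure that the downstream analyses assume:
groups of cellular genomes with order-level compositional signatures and
controlled GC content, niches confounded with taxonomy, mobile genetic
elements whose composition blends a host signal with a family-specific
signal, and planted recent host transfers and compositional outliers.

Every genome is emitted from a phased (codon-position-aware) Markov model
as a sequence of frame-preserving gene blocks separated by short intergenic
spacers, so coding-region analyses (codon usage, word exceptionality) see
realistic phase structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import decode, reverse_complement
from .markov import N_PHASES, PhasedMarkovModel, uniform_model

_GC_VEC = np.array([0.0, 1.0, 1.0, 0.0])

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    """One taxonomic order of cellular genomes."""

    name: str
    niche: str
    gc: float
    perturbation: float
    n_cells: int
    phylum: str = "Euryarchaeota"
    n_genera: int = 2


@dataclass
class FamilySpec:
    """One mobile-element family replicating in a single host order."""

    name: str
    host_order: str
    element_type: str  # "plasmid" | "virus"
    length_range: tuple[int, int]
    signature: float  # magnitude of the family-specific perturbation
    host_weight: float  # blend weight w toward the host signal, in [0, 1]
    n_elements: int


@dataclass
class PlantedEvent:
    """A planted anomaly: a recent host transfer or a compositional outlier."""

    kind: str  # "host_transfer" | "outlier"
    element_id: str
    source_order: str | None = None  # for host_transfer
    scale: float = 3.0  # for outlier: multiple of the group perturbation


@dataclass
class SyntheticSpec:
    groups: list[GroupSpec]
    mge_families: list[FamilySpec] = field(default_factory=list)
    planted_events: list[PlantedEvent] = field(default_factory=list)
    genome_length_range: tuple[int, int] = (60_000, 80_000)
    markov_order: int = 2
    seed: int = 0

    def validate(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        for g in self.groups:
            if not 0.0 < g.gc < 1.0:
                raise ValueError(f"group {g.name}: gc must be in (0, 1)")
            if g.perturbation < 0:
                raise ValueError(f"group {g.name}: perturbation must be >= 0")
        for f in self.mge_families:
            if not 0.0 <= f.host_weight <= 1.0:
                raise ValueError(f"family {f.name}: host_weight must be in [0, 1]")
            if f.host_order not in names:
                raise ValueError(f"family {f.name}: unknown host order {f.host_order}")
            if f.element_type not in ("plasmid", "virus"):
                raise ValueError(f"family {f.name}: bad element type {f.element_type}")
            if f.length_range[0] < 3:
                raise ValueError(f"family {f.name}: lengths must be >= 3")
        if self.genome_length_range[0] < 3:
            raise ValueError("genome lengths must be >= 3")
        for ev in self.planted_events:
            if ev.kind not in ("host_transfer", "outlier"):
                raise ValueError(f"unknown planted event kind {ev.kind}")
            if ev.kind == "host_transfer" and ev.source_order not in names:
                raise ValueError(f"host_transfer source order {ev.source_order} unknown")


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


def _tilt_to_gc(model: PhasedMarkovModel, gc_target: float, tol: float = 1e-6) -> PhasedMarkovModel:
    """Exponentially tilt transition rows toward/away from G+C to hit a target.

    Each row is multiplied by exp(beta * [base is G or C]) and renormalized;
    beta is found by bisection on the model's exact stationary GC, which is
    monotone increasing in beta.
    """
    lo, hi = -40.0, 40.0

    def tilted(beta: float) -> PhasedMarkovModel:
        w = np.exp(beta * _GC_VEC)
        probs = model.probs * w[None, None, :]
        probs /= probs.sum(axis=2, keepdims=True)
        return PhasedMarkovModel(model.order, probs)

    for _ in range(80):
        mid = 0.5 * (lo + hi)
        cand = tilted(mid)
        gc = cand.stationary_gc()
        if abs(gc - gc_target) < tol:
            return cand
        if gc < gc_target:
            lo = mid
        else:
            hi = mid
    return tilted(0.5 * (lo + hi))


def build_group_model(
    base: PhasedMarkovModel, gc_target: float, perturbation: float, seed: SeedLike = 0
) -> PhasedMarkovModel:
    """Derive a group-specific model from a base model.

    The base transition rows are jittered multiplicatively on the log scale
    (magnitude ``perturbation``) to create an order-level signature, then
    exponentially tilted so that the stationary GC matches ``gc_target``.
    With ``perturbation=0`` and a target equal to the base's stationary GC
    the base model is returned unchanged.
    """
    if not 0.0 < gc_target < 1.0:
        raise ValueError(f"gc_target must be in (0, 1), got {gc_target}")
    if perturbation < 0:
        raise ValueError("perturbation must be >= 0")
    if perturbation == 0 and abs(base.stationary_gc() - gc_target) < 1e-9:
        return base.copy()
    probs = base.probs
    if perturbation > 0:
        rng = _rng(seed)
        jitter = np.exp(perturbation * rng.standard_normal(probs.shape))
        probs = probs * jitter
        probs = probs / probs.sum(axis=2, keepdims=True)
    return _tilt_to_gc(PhasedMarkovModel(base.order, probs), gc_target)


def blend_models(
    host: PhasedMarkovModel, family: PhasedMarkovModel, w: float
) -> PhasedMarkovModel:
    """Normalized geometric mixture host**w * family**(1-w), row by row."""
    if host.order != family.order:
        raise ValueError("models must have the same order to blend")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"blend weight must be in [0, 1], got {w}")
    if w == 1.0:
        return host.copy()
    if w == 0.0:
        return family.copy()
    probs = host.probs**w * family.probs ** (1.0 - w)
    sums = probs.sum(axis=2, keepdims=True)
    sums[sums == 0] = 1.0
    return PhasedMarkovModel(host.order, probs / sums)


# ---------------------------------------------------------------------------
# genome emission
# ---------------------------------------------------------------------------


def simulate_genome(
    model: PhasedMarkovModel,
    length: int,
    seed: SeedLike = 0,
    gene_length_mean: int = 900,
    spacer_length: int = 24,
    minus_strand_fraction: float = 0.0,
) -> tuple[str, list[tuple[int, int, str]]]:
    """Emit a genome of exactly ``length`` bases plus frame-consistent CDS.

    The genome alternates gene blocks (lengths multiples of 3, emitted from
    the phased model with phase 0 at the gene start) and short intergenic
    spacers, so annotated CDS tile >= 80% of the sequence.  Genes are placed
    on the + strand; with ``minus_strand_fraction`` > 0 a random subset is
    written reverse-complemented and annotated on the - strand.

    Returns the sequence and a list of 1-based inclusive ``(start, end,
    strand)`` CDS intervals.
    """
    if length < model.order + 1:
        raise ValueError(f"length {length} < order + 1 = {model.order + 1}")
    rng = _rng(seed)
    parts: list[str] = []
    cds: list[tuple[int, int, str]] = []
    pos = 0  # 0-based length emitted so far
    while pos < length:
        remaining = length - pos
        if remaining < 90:
            # tail too short for a gene: pad as intergenic sequence
            parts.append(decode(model.sample(remaining, rng)))
            pos = length
            break
        raw = rng.normal(gene_length_mean, gene_length_mean / 6)
        gene_len = 3 * int(max(30, round(raw / 3)))
        gene_len = min(gene_len, 3 * (remaining // 3))
        block = model.sample(gene_len, rng)
        if minus_strand_fraction > 0 and rng.random() < minus_strand_fraction:
            parts.append(reverse_complement(decode(block)))
            cds.append((pos + 1, pos + gene_len, "-"))
        else:
            parts.append(decode(block))
            cds.append((pos + 1, pos + gene_len, "+"))
        pos += gene_len
        spacer = min(spacer_length, length - pos)
        if spacer > 0:
            parts.append(decode(model.sample(spacer, rng)))
            pos += spacer
    seq = "".join(parts)
    assert len(seq) == length
    return seq, cds


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "id",
    "type",
    "phylum",
    "order",
    "genus",
    "family",
    "host_order",
    "niche",
    "length_bp",
    "gc",
]


@dataclass
class SyntheticDataset:
    """In-memory result of :func:`build_dataset`."""

    spec: SyntheticSpec
    sequences: dict[str, str]
    annotations: dict[str, list[tuple[int, int, str]]]
    metadata: pd.DataFrame
    group_models: dict[str, PhasedMarkovModel]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from . import io as sio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genomes.fasta"
        gff = outdir / "annotations.gff3"
        meta = outdir / "metadata.tsv"
        sio.write_fasta(list(self.sequences.items()), fasta)
        sio.write_gff3(self.annotations, gff)
        self.metadata.to_csv(meta, sep="\t", index=False)
        return {"fasta": fasta, "gff3": gff, "metadata": meta}


def _gc_of(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def build_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate all declared genomes, fully reproducibly from ``spec.seed``."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    base = uniform_model(spec.markov_order)

    events = {ev.element_id: ev for ev in spec.planted_events}
    group_by_name = {g.name: g for g in spec.groups}

    sequences: dict[str, str] = {}
    annotations: dict[str, list[tuple[int, int, str]]] = {}
    rows: list[dict] = []

    def spawn():
        return ss.spawn(1)[0]

    group_models: dict[str, PhasedMarkovModel] = {}
    for g in spec.groups:
        group_models[g.name] = build_group_model(base, g.gc, g.perturbation, spawn())

    # cells
    for g in spec.groups:
        rng = _rng(spawn())
        for i in range(g.n_cells):
            gid = f"{g.name}_cell{i + 1:02d}"
            if gid in sequences:
                raise ValueError(f"duplicate genome id {gid}")
            L = int(rng.integers(*spec.genome_length_range))
            seq, cds = simulate_genome(group_models[g.name], L, spawn())
            sequences[gid] = seq
            annotations[gid] = cds
            rows.append(
                {
                    "id": gid,
                    "type": "cell",
                    "phylum": g.phylum,
                    "order": g.name,
                    "genus": f"{g.name}_g{i % g.n_genera + 1}",
                    "family": "",
                    "host_order": "",
                    "niche": g.niche,
                    "length_bp": L,
                    "gc": round(_gc_of(seq), 4),
                }
            )

    # mobile elements
    for f in spec.mge_families:
        host_group = group_by_name[f.host_order]
        host_model = group_models[f.host_order]
        family_model = build_group_model(host_model, host_group.gc, f.signature, spawn())
        rng = _rng(spawn())
        for i in range(f.n_elements):
            gid = f"{f.name}_{i + 1:02d}"
            if gid in sequences:
                raise ValueError(f"duplicate genome id {gid}")
            ev = events.get(gid)
            if ev is not None and ev.kind == "host_transfer":
                # composition from the source order, label from the target host
                model = blend_models(
                    group_models[ev.source_order], family_model, f.host_weight
                )
            elif ev is not None and ev.kind == "outlier":
                model = build_group_model(
                    host_model,
                    host_group.gc,
                    ev.scale * max(host_group.perturbation, f.signature),
                    spawn(),
                )
            else:
                model = blend_models(host_model, family_model, f.host_weight)
            L = int(rng.integers(*f.length_range))
            seq, cds = simulate_genome(model, L, spawn())
            sequences[gid] = seq
            annotations[gid] = cds
            rows.append(
                {
                    "id": gid,
                    "type": f.element_type,
                    "phylum": host_group.phylum,
                    "order": f.host_order,
                    "genus": "",
                    "family": f.name,
                    "host_order": f.host_order,
                    "niche": host_group.niche,
                    "length_bp": L,
                    "gc": round(_gc_of(seq), 4),
                }
            )

    metadata = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    return SyntheticDataset(spec, sequences, annotations, metadata, group_models)


def simulate_homolog_table(
    dataset: SyntheticDataset, seed: SeedLike = 0
) -> pd.DataFrame:
    """Synthetic pairwise shared-gene counts emulating an all-vs-all
    protein comparison summary.

    Pairs within the same order share genes; cells share many genes with
    large plasmids and megaplasmids of their order but few with small
    plasmids and viruses, and elements of one family share genes with each
    other.  Counts are scaled so that count / (smaller length in kb) lands
    in the intended normalized-weight band.
    """
    rng = _rng(seed)
    meta = dataset.metadata.set_index("id")
    ids = list(meta.index)
    rows = []
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = ids[a_i], ids[b_i]
            ra, rb = meta.loc[a], meta.loc[b]
            min_kb = min(ra.length_bp, rb.length_bp) / 1000.0
            same_order = ra.order == rb.order
            types = {ra.type, rb.type}
            if not same_order:
                w = rng.uniform(0.0, 0.02)
            elif types == {"cell"}:
                w = rng.uniform(0.3, 0.8)
            elif "cell" in types:
                other = rb if ra.type == "cell" else ra
                if other.type == "plasmid" and other.length_bp >= 100_000:
                    w = rng.uniform(0.15, 0.5)  # large plasmids / megaplasmids
                else:
                    w = rng.uniform(0.0, 0.08)  # small plasmids and viruses
            elif ra.family == rb.family:
                w = rng.uniform(0.2, 0.6)
            else:
                w = rng.uniform(0.0, 0.05)
            count = int(round(w * min_kb))
            if count > 0:
                rows.append({"genome_a": a, "genome_b": b, "shared_gene_count": count})
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "shared_gene_count"])


def demo_spec(seed: int = 0) -> SyntheticSpec:
    """Default study conditions: four archaeal-like orders with distinct
    niches and GC levels, seven mobile-element families, one planted recent
    host transfer and three planted compositional outliers."""
    groups = [
        GroupSpec("Halobacteriales", "halophile", 0.62, 0.35, 8, phylum="Euryarchaeota"),
        GroupSpec("Sulfolobales", "extreme thermophile", 0.36, 0.35, 8, phylum="Crenarchaeota"),
        GroupSpec("Thermococcales", "hyperthermophile", 0.45, 0.35, 8, phylum="Euryarchaeota"),
        GroupSpec("Methanococcales", "mesophile", 0.29, 0.35, 8, phylum="Euryarchaeota"),
    ]
    families = [
        FamilySpec("halo_megaplasmid", "Halobacteriales", "plasmid", (150_001, 200_000), 0.25, 0.8, 5),
        FamilySpec("halo_largeplasmid", "Halobacteriales", "plasmid", (100_000, 150_000), 0.25, 0.75, 4),
        FamilySpec("halo_virus", "Halobacteriales", "virus", (30_000, 60_000), 0.3, 0.6, 6),
        FamilySpec("sulfo_pRN", "Sulfolobales", "plasmid", (8_000, 14_000), 0.3, 0.6, 6),
        FamilySpec("sulfo_rudivirus", "Sulfolobales", "virus", (25_000, 35_000), 0.35, 0.55, 6),
        FamilySpec("thermo_pT26", "Thermococcales", "plasmid", (15_000, 25_000), 0.3, 0.7, 6),
        FamilySpec("methano_plasmid", "Methanococcales", "plasmid", (10_000, 22_000), 0.25, 0.75, 6),
    ]
    events = [
        PlantedEvent("host_transfer", "methano_plasmid_01", source_order="Thermococcales"),
        PlantedEvent("outlier", "halo_virus_01", scale=3.0),
        PlantedEvent("outlier", "sulfo_pRN_01", scale=3.0),
        PlantedEvent("outlier", "thermo_pT26_01", scale=3.0),
    ]
    return SyntheticSpec(
        groups=groups,
        mge_families=families,
        planted_events=events,
        genome_length_range=(60_000, 80_000),
        markov_order=2,
        seed=seed,
    )
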