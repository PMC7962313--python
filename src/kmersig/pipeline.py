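"""End-to-end orchestration: simulate/load -> profiles -> exceptionality ->
distances/clustering/ordination -> PERMANOVA -> outliers -> network.

All randomness flows from one master seed through named per-stage
substreams, so partial reruns are stable; every run writes a manifest
listing the configuration, the per-stage artifacts with checksums, and
the attrition counts (genomes in/out of each stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .exceptionality import exceptionality_matrix
from .multivariate import euclidean_distance_matrix, pca, plsda, top_discriminant, ward_cluster
from .network import (
    build_network,
    category_edge_stats,
    filter_edges,
    read_homolog_table,
    write_edge_table,
    write_graphml,
)
from .outliers import outlier_report
from .permanova import permanova_formula
from .profiles import profile_matrix
from .simulate import build_dataset, demo_spec, simulate_homolog_table

logger = logging.getLogger(__name__)

STAGE_NAMES = [
    "input", "profile", "exceptionality", "cluster", "pca", "plsda",
    "permanova", "outliers", "network",
]


@dataclass
class RunConfig:
    """Declarative configuration of a full analysis run."""

    outdir: str = "kmersig_run"
    seed: int = 0
    synthetic: bool = True  # exactly one input source: synthetic xor files
    fasta: str | None = None
    gff3: str | None = None
    metadata: str | None = None
    homolog_table: str | None = None
    k: int = 5
    canonical: bool = False
    markov_order: int = 2
    n_permutations: int = 9999
    permanova_models: list[str] = field(
        default_factory=lambda: [
            "D_5_cells ~ order",
            "D_5_cells ~ gc",
            "D_5_cells ~ niche",
            "D_5_cells ~ order*gc",
            "D_5_cells ~ phylum*order*genus",
            "D_5_mobile ~ host_order",
            "D_5_mobile ~ family",
            "D_5_mobile ~ niche*host_order*gc",
        ]
    )
    plsda_schemes: list[str] = field(default_factory=lambda: ["halophily", "hyperthermophily"])
    plsda_folds: int = 10
    plsda_repeats: int = 10
    plsda_max_components: int = 10
    outlier_confidence: float = 0.95
    edge_filter: float = 0.1
    network_mode: str = "kb"
    stages: list[str] = field(default_factory=lambda: list(STAGE_NAMES))

    def validate(self) -> None:
        if self.synthetic and (self.fasta or self.gff3 or self.metadata):
            raise ValueError("choose synthetic input or files, not both")
        if not self.synthetic and not (self.fasta and self.metadata):
            raise ValueError("file input requires fasta and metadata paths")
        unknown = set(self.stages) - set(STAGE_NAMES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for m in self.permanova_models:
            if "~" not in m:
                raise ValueError(f"bad model string {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def partition_labels(metadata: pd.DataFrame, scheme: str) -> pd.Series:
    """Binary niche partitions.

    ``halophily``: halophile vs non-halophile over all records.
    ``hyperthermophily``: halophiles removed, then the 80 degC split of the
    growth-temperature classes.
    """
    if "niche" not in metadata.columns:
        raise ValueError("metadata has no 'niche' column")
    niche = metadata.set_index("id")["niche"] if "id" in metadata.columns else metadata["niche"]
    unknown = set(niche.unique()) - set(sio.NICHE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown niche values: {sorted(unknown)}")
    if scheme == "halophily":
        return niche.map(lambda n: "halophile" if sio.is_halophile(n) else "non-halophile")
    if scheme == "hyperthermophily":
        kept = niche[~niche.map(sio.is_halophile)]
        n_removed = len(niche) - len(kept)
        if n_removed:
            logger.info("hyperthermophily scheme: removed %d halophiles", n_removed)
        return kept.map(
            lambda n: "hyperthermophile" if sio.is_hyperthermophile(n) else "non-hyperthermophile"
        )
    raise ValueError(f"unknown partition scheme {scheme!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in dependency order; returns the run
    directory.  Any stage failure raises, naming the stage."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict] = {}
    counts: dict[str, dict] = {}

    def record(stage: str, name: str, path: Path, n_rows: int | None = None) -> None:
        artifacts.setdefault(stage, {})[name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
            **({"n_rows": n_rows} if n_rows is not None else {}),
        }

    current = "input"
    try:
        # ---- input -------------------------------------------------------
        if config.synthetic:
            dataset = build_dataset(demo_spec(seed=_stage_seed(config.seed, "simulate")))
            paths = dataset.write(outdir / "data")
            for name, p in paths.items():
                record("input", name, p)
            metadata = dataset.metadata
            records = sio.load_genomes(paths["fasta"], paths["gff3"], metadata)
            homologs = simulate_homolog_table(dataset, seed=_stage_seed(config.seed, "homologs"))
        else:
            metadata = sio.read_metadata(config.metadata)
            records = sio.load_genomes(config.fasta, config.gff3, metadata)
            homologs = (
                read_homolog_table(config.homolog_table, known_ids=metadata["id"])
                if config.homolog_table
                else None
            )
        for model_str in config.permanova_models:
            for term in model_str.split("~")[1].split("*"):
                if term.strip() not in metadata.columns:
                    raise ValueError(f"model {model_str!r}: unknown column {term.strip()!r}")
        counts["input"] = {"genomes": len(records)}
        meta_idx = metadata.set_index("id")
        cells = [r for r in records if r.element_type == "cell"]
        mobiles = [r for r in records if r.element_type != "cell"]

        # ---- profiles ----------------------------------------------------
        matrices: dict[str, pd.DataFrame] = {}
        if "profile" in config.stages:
            current = "profile"
            for name, subset in [("cells", cells), ("mobile", mobiles), ("joint", records)]:
                if len(subset) < 2:
                    continue
                M = profile_matrix(subset, k=config.k, canonical=config.canonical)
                matrices[name] = M
                p = outdir / f"profiles_{name}.tsv"
                M.to_csv(p, sep="\t")
                record("profile", name, p, len(M))
            counts["profile"] = {k: len(v) for k, v in matrices.items()}

        # ---- exceptionality ---------------------------------------------
        ematrices: dict[str, pd.DataFrame] = {}
        if "exceptionality" in config.stages:
            current = "exceptionality"
            for name, subset in [("cells", cells), ("mobile", mobiles)]:
                if len(subset) < 2:
                    continue
                E = exceptionality_matrix(subset, k=config.k, m=config.markov_order)
                ematrices[name] = E
                p = outdir / f"exceptionality_{name}.tsv"
                E.to_csv(p, sep="\t")
                record("exceptionality", name, p, len(E))
            counts["exceptionality"] = {
                name: {"in": len(subset), "out": len(ematrices.get(name, []))}
                for name, subset in [("cells", cells), ("mobile", mobiles)]
            }

        # ---- distances + clustering -------------------------------------
        distances = {}
        if "cluster" in config.stages:
            current = "cluster"
            for name, M in {**matrices, **{f"{k}_e": v for k, v in ematrices.items()}}.items():
                D = euclidean_distance_matrix(M, kind=name)
                distances[name] = D
                dend = ward_cluster(D)
                p = outdir / f"dendrogram_{name}.nwk"
                p.write_text(dend.to_newick() + "\n")
                record("cluster", name, p)

        # ---- PCA ---------------------------------------------------------
        if "pca" in config.stages and matrices:
            current = "pca"
            for name, M in matrices.items():
                res = pca(M)
                p = outdir / f"pca_scores_{name}.tsv"
                res.scores.iloc[:, :10].to_csv(p, sep="\t")
                record("pca", name, p, len(res.scores))

        # ---- PLS-DA ------------------------------------------------------
        if "plsda" in config.stages and matrices:
            current = "plsda"
            seed = _stage_seed(config.seed, "plsda")
            for scheme in config.plsda_schemes:
                labels_all = partition_labels(metadata, scheme)
                for name in ("cells", "mobile"):
                    if name not in matrices:
                        continue
                    M = matrices[name]
                    keep = [i for i in M.index if i in labels_all.index]
                    labels = labels_all.loc[keep]
                    if labels.nunique() < 2:
                        logger.warning("plsda %s/%s: single class; skipped", scheme, name)
                        continue
                    res = plsda(
                        M.loc[keep],
                        labels,
                        n_grid=range(1, config.plsda_max_components + 1),
                        folds=config.plsda_folds,
                        repeats=config.plsda_repeats,
                        seed=seed,
                    )
                    top = top_discriminant(res, n=10)
                    p = outdir / f"plsda_{scheme}_{name}_top10.tsv"
                    top.to_csv(p, sep="\t", index=False)
                    record("plsda", f"{scheme}_{name}", p, len(top))

        # ---- PERMANOVA ---------------------------------------------------
        if "permanova" in config.stages and distances:
            current = "permanova"
            seed = _stage_seed(config.seed, "permanova")
            results = []
            for model_str in config.permanova_models:
                response = model_str.split("~")[0].strip()
                key = response.replace("D_5_", "").replace("D_", "")
                if key not in distances:
                    logger.warning("no distance matrix for %r; model skipped", model_str)
                    continue
                res = permanova_formula(
                    distances[key], metadata, model_str,
                    n_perm=config.n_permutations, seed=seed,
                )
                t = res.table.reset_index()
                t.insert(0, "model", res.model)
                results.append(t)
            if results:
                table = pd.concat(results, ignore_index=True)
                p = outdir / "permanova.tsv"
                table.to_csv(p, sep="\t", index=False)
                record("permanova", "table", p, len(table))

        # ---- outliers ----------------------------------------------------
        if "outliers" in config.stages and "mobile" in matrices:
            current = "outliers"
            M = matrices["mobile"]
            fams = meta_idx.loc[M.index, "family"]
            report = outlier_report(M, fams, confidence=config.outlier_confidence)
            p = outdir / "outliers.tsv"
            report.table.to_csv(p, sep="\t", index=False)
            record("outliers", "table", p, len(report.table))
            pj = outdir / "outliers_fit.json"
            pj.write_text(
                json.dumps(
                    {
                        "shape": report.shape,
                        "scale": report.scale,
                        "confidence": report.confidence,
                        "threshold": report.threshold,
                        "n_outliers": report.n_outliers,
                        "excluded_singletons": report.excluded,
                    },
                    indent=2,
                )
            )
            record("outliers", "fit", pj)
            counts["outliers"] = {"flagged": report.n_outliers}

        # ---- network -----------------------------------------------------
        if "network" in config.stages and homologs is not None and len(homologs):
            current = "network"
            G = build_network(homologs, metadata, mode=config.network_mode)
            G = filter_edges(G, config.edge_filter)
            p = outdir / "network_edges.tsv"
            write_edge_table(G, p)
            record("network", "edges", p, G.number_of_edges())
            pg = outdir / "network.graphml"
            write_graphml(G, pg)
            record("network", "graphml", pg)
            stats = category_edge_stats(G)
            ps = outdir / "network_category_stats.tsv"
            stats.to_csv(ps, sep="\t", index=False)
            record("network", "category_stats", ps, len(stats))
    except Exception as exc:
        logger.error("stage %r failed: %s", current, exc)
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    config_dict = asdict(config)
    manifest = {
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": [s for s in STAGE_NAMES if s in artifacts],
        "artifacts": artifacts,
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
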