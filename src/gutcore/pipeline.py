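"""End-to-end orchestration: ingest -> core -> co-abundance -> per-contrast
ordination/MANOVA and LEfSe -> phenotype correlations -> phylogeny, with a
YAML config, a run log listing every applied threshold, a manifest of output
hashes, and (for synthetic inputs) a truth-recovery report.

Outputs are written once into the configured directory; reruns with the same
config and inputs are bit-identical (all stochastic stages are seeded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .cag import build_groups, intergroup_summary, significant_edges, spearman_matrix
from .core import core_summary, identify_core, prevalence
from .io import (
    REQUIRED_METADATA_COLUMNS,
    GenusCountTable,
    collapse_to_genus,
    filter_otus,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    to_relative,
)
from .lefse import run_lefse
from .ordination import manova_test, pca
from .phenotype import correlate_pcs
from .phylogeny import bootstrap_support, p_distance, read_alignment, write_newick
from .simulate import (
    Effect,
    PhenoDef,
    SyntheticConfig,
    generate_community,
    simulate_alignment,
    split_into_otus,
    truth_report,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetSpec",
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "make_fixture",
]

LOG2_PSEUDOCOUNT = 1e-6  # pseudocount for log2 heat-map exports


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class DatasetSpec:
    id: str
    otu_table: str
    taxonomy: str
    confidence: float = 0.8
    format: str = "tsv"


@dataclass
class PipelineConfig:
    datasets: list[DatasetSpec]
    metadata: str
    output_dir: str
    alignment: str | None = None
    truth: str | None = None
    core_prevalence: float = 0.5
    r_min: float = 0.5
    q_max: float = 0.001
    alpha: float = 0.05
    lda_min: float = 2.0
    pheno_q: float = 0.1
    manova_k: int = 2
    pheno_k: int = 10
    bootstrap_reps: int = 1000
    seed: int = 0
    contrasts: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        for name, value, lo, hi in (
            ("core_prevalence", self.core_prevalence, 0.0, 1.0),
            ("r_min", self.r_min, 0.0, 1.0),
            ("q_max", self.q_max, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
            ("pheno_q", self.pheno_q, 0.0, 1.0),
        ):
            if not lo <= value <= hi:
                raise ValueError(f"threshold {name}={value} outside [{lo}, {hi}]")
        if self.lda_min < 0:
            raise ValueError("lda_min must be >= 0")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        base = Path(path).parent
        with open(path) as fh:
            doc = yaml.safe_load(fh)

        def _resolve(p):
            return str((base / p)) if p and not Path(p).is_absolute() else p

        datasets = [
            DatasetSpec(
                id=d["id"],
                otu_table=_resolve(d["otu_table"]),
                taxonomy=_resolve(d["taxonomy"]),
                confidence=float(d.get("confidence", 0.8)),
                format=d.get("format", "tsv"),
            )
            for d in doc["datasets"]
        ]
        thresholds = doc.get("thresholds", {})
        components = doc.get("components", {})
        return cls(
            datasets=datasets,
            metadata=_resolve(doc["metadata"]),
            output_dir=_resolve(doc["output_dir"]),
            alignment=_resolve(doc.get("alignment")),
            truth=_resolve(doc.get("truth")),
            core_prevalence=float(thresholds.get("core_prevalence", 0.5)),
            r_min=float(thresholds.get("r_min", 0.5)),
            q_max=float(thresholds.get("q_max", 0.001)),
            alpha=float(thresholds.get("alpha", 0.05)),
            lda_min=float(thresholds.get("lda_min", 2.0)),
            pheno_q=float(thresholds.get("pheno_q", 0.1)),
            manova_k=int(components.get("manova_k", 2)),
            pheno_k=int(components.get("pheno_k", 10)),
            bootstrap_reps=int(doc.get("bootstrap_reps", 1000)),
            seed=int(doc.get("seed", 0)),
            contrasts=list(doc.get("contrasts", [])),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


class _Stage:
    """Context manager that rebrands any stage failure with the stage name."""

    def __init__(self, name: str, detail: str = ""):
        self.name = name
        self.detail = detail

    def __enter__(self):
        logger.info("stage %s started %s", self.name, self.detail)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(
                f"stage {self.name!r} failed ({self.detail}): {exc}"
            ) from exc
        return False


def _contrast_subset(meta: pd.DataFrame, contrast: dict) -> tuple[pd.Index, pd.Series]:
    column = contrast["column"]
    if column not in meta.columns:
        raise ValueError(f"contrast column {column!r} missing from metadata")
    mask = pd.Series(True, index=meta.index)
    for col, val in (contrast.get("subset") or {}).items():
        if col not in meta.columns:
            raise ValueError(f"contrast subset column {col!r} missing from metadata")
        mask &= meta[col].astype(str) == str(val)
    levels = [str(v) for v in contrast["levels"]]
    labels = meta[column].astype(str)
    mask &= labels.isin(levels)
    return meta.index[mask], labels[mask]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gutcore")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    written: list[Path] = [log_path]

    def emit(frame: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / name
        _write_tsv(frame, path, index=index)
        written.append(path)

    try:
        for key in (
            "core_prevalence",
            "r_min",
            "q_max",
            "alpha",
            "lda_min",
            "pheno_q",
        ):
            logger.info("threshold %s=%s", key, getattr(config, key))
        logger.info("threshold log2_pseudocount=%s", LOG2_PSEUDOCOUNT)

        # ingest ------------------------------------------------------------
        with _Stage("ingest", config.metadata):
            meta = read_metadata(config.metadata)
            for col in REQUIRED_METADATA_COLUMNS:
                if col not in meta.columns:
                    raise ValueError(f"missing metadata column {col!r}")
            dataset_tables: dict[str, GenusCountTable] = {}
            for ds in config.datasets:
                otu = read_otu_table(ds.otu_table, format=ds.format)
                tax = read_taxonomy(ds.taxonomy, confidence_threshold=ds.confidence)
                logger.info(
                    "threshold confidence[%s]=%s", ds.id, ds.confidence
                )
                filtered = filter_otus(otu)
                dataset_tables[ds.id] = collapse_to_genus(filtered, tax)
            all_genera = sorted(
                set().union(*(t.counts.index for t in dataset_tables.values()))
            )
            blocks, residuals = [], []
            for ds_id, t in dataset_tables.items():
                blocks.append(t.counts.reindex(all_genera, fill_value=0))
                residuals.append(t.residual)
            combined = GenusCountTable(
                counts=pd.concat(blocks, axis=1),
                residual=pd.concat(residuals),
                phylum={
                    g: ph
                    for t in dataset_tables.values()
                    for g, ph in t.phylum.items()
                },
            )
            missing = [s for s in combined.counts.columns if s not in meta.index]
            if missing:
                raise ValueError(f"samples missing from metadata: {missing[:5]}")
            abund = to_relative(combined)
            emit(combined.counts, "genus_counts.tsv")

        # core ----------------------------------------------------------------
        with _Stage("core"):
            healthy = [
                s
                for s in abund.sample_ids
                if str(meta.loc[s, "health"]) == "healthy"
            ]
            if not healthy:
                raise ValueError("no healthy samples in metadata")
            prev = prevalence(abund, healthy)
            mean_ab = abund.rel_abund[healthy].mean(axis=1)
            core = identify_core(prev, mean_ab, threshold=config.core_prevalence)
            summary = core_summary(core, dataset_tables)
            core_out = core.entries.copy()
            core_out["phylum"] = [abund.phylum.get(g, "") for g in core_out["genus"]]
            emit(core_out, "core_genera.tsv", index=False)
            heat = np.log2(
                abund.rel_abund.loc[core.genera, healthy] + LOG2_PSEUDOCOUNT
            )
            emit(heat, "core_heatmap_log2.tsv")
            (outdir / "core_summary.json").write_text(
                json.dumps(summary, indent=1, sort_keys=True)
            )
            written.append(outdir / "core_summary.json")
            if len(core) < 2:
                raise ValueError("fewer than 2 core genera; nothing to analyse")

        # co-abundance --------------------------------------------------------
        with _Stage("coabundance"):
            corr = spearman_matrix(
                abund.rel_abund.loc[core.genera],
                samples=healthy,
                r_min=config.r_min,
                q_max=config.q_max,
            )
            grouping = build_groups(corr, prev.loc[core.genera])
            emit(corr.to_frame(), "correlation_matrix.tsv")
            emit(significant_edges(corr), "edges.tsv", index=False)
            grp_frame = pd.DataFrame(
                [
                    (g, gid, float(prev.loc[g]))
                    for gid, members in grouping.groups.items()
                    for g in members
                ],
                columns=["genus", "group", "prevalence"],
            )
            emit(grp_frame, "coabundance_groups.tsv", index=False)
            emit(intergroup_summary(grouping, corr), "intergroup_summary.tsv", index=False)

        # per-contrast ordination + MANOVA + LEfSe -----------------------------
        manova_rows = []
        lefse_selected: dict[str, list[str]] = {}
        for contrast in config.contrasts:
            name = contrast.get("name", contrast["column"])
            with _Stage("contrast", name):
                samples, labels = _contrast_subset(meta, contrast)
                samples = [s for s in samples if s in abund.rel_abund.columns]
                labels = labels.loc[samples]
                counts = labels.value_counts()
                if len(counts) < 2 or counts.min() < 2:
                    raise ValueError(
                        f"contrast {name!r}: need >=2 samples in each of 2 levels"
                    )
                X = abund.rel_abund.loc[core.genera, samples].T
                ord_res = pca(X)
                emit(ord_res.scores, f"pca_scores_{name}.tsv")
                man = manova_test(ord_res, labels.to_numpy(), k=config.manova_k)
                manova_rows.append(
                    (
                        name,
                        man.wilks_lambda,
                        man.statistic,
                        man.df,
                        man.p,
                        man.n_components,
                    )
                )
                lefse = run_lefse(
                    X,
                    labels.to_numpy(),
                    alpha=config.alpha,
                    lda_min=config.lda_min,
                    seed=config.seed,
                )
                tab = lefse.table.copy()
                tab["group"] = [grouping.partition.get(g, "") for g in tab.index]
                emit(tab, f"lefse_{name}.tsv")
                lefse_selected[name] = lefse.selected
        if manova_rows:
            emit(
                pd.DataFrame(
                    manova_rows,
                    columns=["contrast", "wilks_lambda", "chi2", "df", "p", "k"],
                ),
                "manova.tsv",
                index=False,
            )

        # phenotype correlations ----------------------------------------------
        with _Stage("phenotype"):
            param_cols = [
                c for c in meta.columns if c not in REQUIRED_METADATA_COLUMNS
            ]
            if param_cols:
                params = meta[param_cols].apply(pd.to_numeric, errors="coerce")
                with_params = params.dropna(how="all").index
                samples = [s for s in abund.sample_ids if s in with_params]
                if len(samples) >= 3:
                    X = abund.rel_abund.loc[core.genera, samples].T
                    ord_all = pca(X)
                    pheno = correlate_pcs(
                        ord_all,
                        params.loc[samples],
                        k_components=config.pheno_k,
                        q_max=config.pheno_q,
                    )
                    emit(pheno, "phenotype_correlations.tsv", index=False)

        # phylogeny -------------------------------------------------------------
        if config.alignment:
            with _Stage("phylogeny", config.alignment):
                ids, arr = read_alignment(config.alignment)
                keep = [i for i, t in enumerate(ids) if t in set(core.genera)]
                if len(keep) >= 2:
                    sub = ([ids[i] for i in keep], arr[keep])
                    dm = p_distance(sub)
                    emit(
                        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids),
                        "core_distances.tsv",
                    )
                    tree, _ = bootstrap_support(
                        sub, n_reps=config.bootstrap_reps, seed=config.seed
                    )
                    write_newick(tree, outdir / "core_tree.nwk")
                    written.append(outdir / "core_tree.nwk")
                else:
                    logger.warning("fewer than 2 core genera in alignment; skipping tree")

        # truth recovery ---------------------------------------------------------
        if config.truth:
            with _Stage("recovery", config.truth):
                from .simulate import load_truth

                truth = load_truth(config.truth)
                found = set(core.genera)
                planted = set(truth.core_genera)
                overlap = sorted(found & planted & set(truth.group_partition))
                report = {
                    "core_planted": len(planted),
                    "core_found": len(found),
                    "core_jaccard": (
                        len(found & planted) / len(found | planted)
                        if found | planted
                        else 1.0
                    ),
                    "core_missing": sorted(planted - found),
                    "core_extra": sorted(found - planted),
                    "grouping_ari": (
                        float(
                            adjusted_rand_score(
                                [truth.group_partition[g] for g in overlap],
                                [grouping.partition[g] for g in overlap],
                            )
                        )
                        if len(overlap) >= 2
                        else float("nan")
                    ),
                    "lefse": {},
                }
                for contrast in config.contrasts:
                    name = contrast.get("name", contrast["column"])
                    column = contrast["column"]
                    levels = {str(v) for v in contrast["levels"]}
                    planted_eff = {
                        e.genus
                        for e in truth.effects
                        if e.column == column and str(e.level) in levels
                    }
                    sel = set(lefse_selected.get(name, []))
                    report["lefse"][name] = {
                        "planted": sorted(planted_eff),
                        "selected": sorted(sel),
                        "sensitivity": (
                            len(sel & planted_eff) / len(planted_eff)
                            if planted_eff
                            else float("nan")
                        ),
                        "false_selections": sorted(sel - planted_eff),
                    }
                (outdir / "recovery.json").write_text(
                    json.dumps(report, indent=1, sort_keys=True)
                )
                written.append(outdir / "recovery.json")

        # manifest ------------------------------------------------------------
        handler.flush()
        config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
        manifest = {
            "gutcore_version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "output_hashes": {
                p.name: _sha256(p) for p in sorted(set(written)) if p.name != "run.log"
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
        return outdir
    finally:
        root.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# fixture construction
# ---------------------------------------------------------------------------


def _cohort_design() -> tuple[pd.DataFrame, tuple[Effect, ...], tuple[PhenoDef, ...]]:
    """Metadata layout for the cohort fixture: three pseudo-cohorts
    (48/34/19 healthy plus 32/72 diseased; 205 samples, 101 healthy)."""
    rows: list[tuple[str, str, str, str, str]] = []

    def block(n, dataset, age, sex, strain, health):
        rows.extend((dataset, age, sex, strain, health) for _ in range(n))

    block(40, "PRO", "12", "male", "C57BL/6J", "healthy")
    block(8, "PRO", "24", "male", "C57BL/6J", "healthy")
    block(8, "PRO", "24", "male", "C57BL/6J", "MS")
    block(24, "PRO", "24", "male", "C57BL/6J", "MS_probiotics")
    block(11, "CUG", "4", "male", "ICR", "healthy")
    block(12, "CUG", "12", "male", "ICR", "healthy")
    block(11, "CUG", "24", "male", "ICR", "healthy")
    block(36, "CUG", "12", "male", "ICR", "APG")
    block(36, "CUG", "24", "male", "ICR", "APG")
    block(10, "FMT", "8", "male", "C57BL/6J", "healthy")
    block(9, "FMT", "8", "female", "C57BL/6J", "healthy")
    labels = pd.DataFrame(
        rows, columns=["dataset_id", "age_weeks", "sex", "strain", "health"]
    )

    # qualitative mirror of the reported shifts: disease depletes the
    # lactate/acetate group (G2), accelerated growth raises G3, age and sex
    # shift a handful of genera
    effects = (
        Effect("Genus023", "health", "MS", -1.5),  # G2 member
        Effect("Genus024", "health", "MS", -1.5),
        Effect("Genus003", "health", "MS", -1.0),  # G1 member
        Effect("Genus029", "health", "APG", 1.5),  # G3 members
        Effect("Genus030", "health", "APG", 1.5),
        Effect("Genus001", "health", "APG", -1.0),
        Effect("Genus005", "age_weeks", "24", 1.0),
        Effect("Genus006", "age_weeks", "24", 1.0),
        Effect("Genus025", "age_weeks", "4", -1.0),
        Effect("Genus034", "sex", "female", 1.0),
        Effect("Genus035", "sex", "female", 1.0),
    )
    pheno_defs = (
        PhenoDef("fasting_glucose", (0.0, -1.0, 0.5, 0.0, 0.0), 0.5),
        PhenoDef("cecal_butyrate", (1.0, 0.3, 0.0, 0.0, 0.0), 0.5),
        PhenoDef("body_weight", (-0.5, -0.5, 0.5, 0.0, 0.0), 0.5),
        PhenoDef("serum_adiponectin", (0.5, 1.0, 0.0, 0.0, 0.0), 0.5),
    )
    return labels, effects, pheno_defs


def _tiny_design() -> tuple[pd.DataFrame, tuple[Effect, ...], tuple[PhenoDef, ...]]:
    rows = []
    for i in range(8):
        rows.append(("T", "12", "male" if i % 2 else "female", "C57BL/6J", "healthy"))
    for _ in range(4):
        rows.append(("T", "12", "male", "C57BL/6J", "MS"))
    labels = pd.DataFrame(
        rows, columns=["dataset_id", "age_weeks", "sex", "strain", "health"]
    )
    effects = (Effect("Genus002", "health", "MS", -2.0),)
    pheno_defs = (
        PhenoDef("fasting_glucose", (-1.0, 0.5, 0.0), 0.5),
        PhenoDef("cecal_butyrate", (1.0, 0.0, 0.0), 0.5),
    )
    return labels, effects, pheno_defs


def make_fixture(size: str, seed: int, outdir) -> Path:
    """Write a complete synthetic input bundle plus a ready-to-run config.

    size='tiny': 12 samples x 15 genera, one pseudo-dataset, fast smoke runs.
    size='cohort': 205 samples x 120 genera in three pseudo-datasets
    (48/34/19 healthy mirroring the three-cohort layout, 101 healthy total).
    Returns the path to the written config.yaml.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if size == "tiny":
        labels, effects, pheno_defs = _tiny_design()
        cfg = SyntheticConfig(
            n_samples=len(labels),
            n_genera=15,
            group_sizes=(4, 3, 2),
            factor_corr=np.eye(3),
            depth=5000,
            class_labels=labels,
            effects=effects,
            pheno_defs=pheno_defs,
            seed=int(seed),
        )
        contrasts = [
            {"name": "health_T", "column": "health", "levels": ["healthy", "MS"]}
        ]
        boot = 50
    elif size == "cohort":
        labels, effects, pheno_defs = _cohort_design()
        cfg = SyntheticConfig(
            n_samples=len(labels),
            n_genera=120,
            group_sizes=(22, 6, 5, 3, 1),
            class_labels=labels,
            effects=effects,
            pheno_defs=pheno_defs,
            seed=int(seed),
        )
        contrasts = [
            {
                "name": "age_PRO",
                "column": "age_weeks",
                "levels": ["12", "24"],
                "subset": {"dataset_id": "PRO", "health": "healthy"},
            },
            {
                "name": "age_CUG",
                "column": "age_weeks",
                "levels": ["4", "24"],
                "subset": {"dataset_id": "CUG", "health": "healthy"},
            },
            {
                "name": "sex_FMT",
                "column": "sex",
                "levels": ["male", "female"],
                "subset": {"dataset_id": "FMT"},
            },
            {
                "name": "health_PRO",
                "column": "health",
                "levels": ["healthy", "MS"],
                "subset": {"dataset_id": "PRO"},
            },
            {
                "name": "health_CUG",
                "column": "health",
                "levels": ["healthy", "APG"],
                "subset": {"dataset_id": "CUG"},
            },
        ]
        boot = 1000
    else:
        raise ValueError(f"unknown fixture size {size!r}")

    counts, metadata, truth = generate_community(cfg)
    datasets = sorted(metadata["dataset_id"].unique())
    ds_entries = []
    for ds in datasets:
        cols = metadata.index[metadata["dataset_id"] == ds]
        otu_counts, flags, taxonomy = split_into_otus(
            counts[cols], seed=int(seed) + hash(ds) % 1000
        )
        otu_path = outdir / f"otus_{ds}.tsv"
        flag_series = [
            ";".join(sorted(flags.get(o, ()))) for o in otu_counts.index
        ]
        out = otu_counts.copy()
        out["flags"] = flag_series
        out.to_csv(otu_path, sep="\t")
        tax_path = outdir / f"taxonomy_{ds}.tsv"
        with open(tax_path, "w") as fh:
            for _, row in taxonomy.iterrows():
                fh.write(
                    f"{row.otu}\t-\tBacteria\tdomain\t1.0\t{row.phylum}\tphylum\t0.99"
                    f"\t{row.genus}\tgenus\t{row.confidence}\n"
                )
        # the FMT-style cohort plays the MiSeq role with the stricter cutoff
        conf = 0.8 if ds == "FMT" else 0.5
        ds_entries.append(
            {
                "id": ds,
                "otu_table": otu_path.name,
                "taxonomy": tax_path.name,
                "confidence": conf,
            }
        )

    meta_path = outdir / "metadata.tsv"
    metadata.to_csv(meta_path, sep="\t")

    aln = simulate_alignment(list(counts.index), length=300, seed=int(seed))
    aln_path = outdir / "alignment.fasta"
    with open(aln_path, "w") as fh:
        for name, seq in aln.items():
            fh.write(f">{name}\n{seq}\n")

    truth_path = outdir / "truth.json"
    truth_report(truth, truth_path)

    config_doc = {
        "seed": int(seed),
        "output_dir": "results",
        "metadata": meta_path.name,
        "alignment": aln_path.name,
        "truth": truth_path.name,
        "datasets": ds_entries,
        "bootstrap_reps": boot,
        "thresholds": {
            "core_prevalence": 0.5,
            "r_min": 0.5,
            "q_max": 0.001,
            "alpha": 0.05,
            "lda_min": 2.0,
            "pheno_q": 0.1,
        },
        "components": {"manova_k": 2, "pheno_k": 10},
        "contrasts": contrasts,
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config_doc, fh, sort_keys=False)
    return config_path
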