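"""End-to-end orchestration: simulate (or load) a study, build the trait
matrix, run the trajectory, convergence and classification analyses, and
emit report tables.

Every stochastic stage derives its seed from the master seed by stable
hashing of its label, so whole runs are bitwise reproducible while theta
and delta-L themselves stay deterministic given the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import convergence as _convergence
from . import io as _io
from . import morphometry as _morph
from . import simulate as _sim
from . import trajectory as _traj


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either a specimen table path (assembled, raw-scale traits plus
    metadata) or simulation parameters supply the data. ``scaling_population``
    names the rows over which standardization statistics are computed:
    'museum' (default, the comparative analyses) or 'all'.
    """

    specimen_table: str | None = None
    tree: str | None = None
    radiation: _sim.RadiationParams | None = None
    scaling_population: str = "museum"
    t_variant: str = "welch"
    n_perm: int = 999
    n_boot: int = 999
    n_perm_convergence: int = 199
    alpha: float = 0.05
    min_n: int = 2
    seed: int = 0
    run_convergence: bool = True
    run_signature_scan: bool = False
    run_sex_assignment: bool = False
    outdir: str | None = None

    def __post_init__(self):
        if self.n_perm < 99 or self.n_boot < 99:
            raise ValueError("n_perm and n_boot must be at least 99")
        if self.t_variant not in ("welch", "pooled"):
            raise ValueError(f"unknown t variant {self.t_variant!r}")
        if self.scaling_population not in ("museum", "all"):
            raise ValueError(f"unknown scaling population {self.scaling_population!r}")
        if self.specimen_table is not None and not Path(self.specimen_table).exists():
            raise ValueError(f"specimen table not found: {self.specimen_table}")


@dataclass
class RunReport:
    quartet_table: pd.DataFrame
    summary: dict
    outlier_tables: dict
    convergence_table: pd.DataFrame | None
    classification_table: pd.DataFrame | None
    pca_summary: _morph.PCASummary
    traits: _morph.TraitMatrix
    metadata: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def prepare_study(study: _sim.SimulatedStudy, imputation_rank: int = 3) -> pd.DataFrame:
    """Morphometry stages: mirror, GPA per girdle, impute, size-correct, assemble.

    Returns the raw-scale assembled 132-column trait table (standardize
    over the analysis population afterwards).
    """
    gpa_results, id_lists = {}, {}
    for structure in ("pectoral", "pelvic"):
        ids = [sid for sid in study.latent.index if structure in study.landmarks.get(sid, {})]
        configs = []
        for sid in ids:
            cfg = study.landmarks[sid][structure]
            if cfg.side == "right":
                cfg = _morph.mirror_configuration(cfg)
            configs.append(cfg)
        gpa_results[structure] = _morph.gpa(configs)
        id_lists[structure] = ids
    pel_ids = id_lists["pelvic"]
    completed = _morph.impute_missing(study.linear.loc[pel_ids], q=imputation_rank)
    sizes = pd.Series(gpa_results["pelvic"].centroid_sizes, index=pel_ids)
    corrected = _morph.size_correct(completed, sizes)
    return _morph.assemble_traits(
        gpa_results["pectoral"], id_lists["pectoral"],
        gpa_results["pelvic"], pel_ids, corrected,
    )


def _load(config: RunConfig):
    """Return (raw trait table, metadata, tree-or-None) from file or simulation."""
    if config.specimen_table is not None:
        ds = _io.read_specimen_table(config.specimen_table)
        report = _io.validate_dataset(ds)
        if not report.ok:
            raise ValueError(f"dataset invalid: {report.errors}")
        tree = _io.read_tree(config.tree) if config.tree else None
        return ds.traits, ds.metadata, tree
    params = config.radiation or _sim.RadiationParams(seed=config.seed)
    study = _sim.simulate_study(params)
    raw = prepare_study(study)
    return raw, study.metadata.loc[raw.index], study.tree


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every analysis stage and assemble the run report."""
    raw, metadata, tree = _load(config)
    museum = metadata.index[metadata["source"] == "museum"]
    scale_rows = museum if config.scaling_population == "museum" else raw.index
    traits = _morph.standardize(raw.loc[scale_rows])
    scaled_all = traits.project(raw)

    museum_scaled = scaled_all.loc[museum]
    museum_meta = metadata.loc[museum]
    quartets = _traj.enumerate_quartets(museum_meta, min_n=config.min_n)
    rows = []
    for q in quartets:
        res = _traj.analyze_quartet(
            q, museum_scaled, museum_meta,
            n_perm=config.n_perm, n_boot=config.n_boot,
            seed=_traj.derive_seed(config.seed, q.label),
            alpha=config.alpha, variant=config.t_variant,
        )
        rows.append(
            {"ecomorph_1": q.ecomorphs[0], "ecomorph_2": q.ecomorphs[1],
             "island_1": q.islands[0], "island_2": q.islands[1],
             "theta": res.theta, "delta_L": res.delta_L,
             "p_parallel": res.p_parallel, "p_length": res.p_length,
             "p_orthogonal": res.p_orthogonal, "classification": res.classification,
             "n_perm": res.n_perm, "n_boot": res.n_boot, "seed": res.seed}
        )
    quartet_table = pd.DataFrame(rows)
    summary = {
        "n_quartets": len(quartets),
        "mean_theta": float(quartet_table["theta"].mean()) if len(rows) else float("nan"),
        "sd_theta": float(quartet_table["theta"].std(ddof=1)) if len(rows) > 1 else float("nan"),
        "classification_counts": quartet_table["classification"].value_counts().to_dict() if len(rows) else {},
        "n_length_indistinguishable": int((quartet_table["p_length"] >= config.alpha).sum()) if len(rows) else 0,
    }

    # outlier scans: per-quartet-contrast signature traits on the sharpest contrast,
    # plus experiment contrasts where present
    outlier_tables = {}
    for q in quartets:
        v1, v2 = _traj.quartet_vectors(q, museum_scaled, museum_meta, variant=config.t_variant)
        for v, isl in ((v1, q.islands[0]), (v2, q.islands[1])):
            key = f"{q.ecomorphs[0]}_vs_{q.ecomorphs[1]}_{isl}"
            if key in outlier_tables:
                continue
            try:
                scan = _traj.outlier_traits(v)
            except ValueError:
                continue
            outlier_tables[key] = pd.DataFrame(
                {"trait": scan.columns, "t": v.t_values, "z": scan.z_scores,
                 "flagged": [c in scan.flagged for c in scan.columns]}
            )

    convergence_table = None
    if config.run_convergence:
        species_means = museum_scaled.groupby(museum_meta["species"]).mean()
        if tree is not None:
            conv_rows = []
            for eco in sorted(museum_meta["ecomorph"].dropna().unique()):
                focal = sorted(museum_meta.loc[museum_meta["ecomorph"] == eco, "species"].unique())
                if len(focal) < 2:
                    continue
                seed = _traj.derive_seed(config.seed, f"convergence|{eco}")
                if config.run_signature_scan:
                    res = _convergence.signature_scan(
                        species_means, tree, focal,
                        n_perm=config.n_perm_convergence, seed=seed, alpha=config.alpha,
                        focal_label=eco,
                    )
                    n_sig = int(res.per_trait["signature"].sum())
                else:
                    res = _convergence.wheatsheaf(
                        species_means, tree, focal,
                        n_perm=config.n_perm_convergence, seed=seed, focal_label=eco,
                    )
                    n_sig = -1
                conv_rows.append({"ecomorph": eco, "w": res.w, "p": res.p,
                                  "n_signature_traits": n_sig})
            convergence_table = pd.DataFrame(conv_rows)

    pca = _morph.pca_variance(scaled_all.loc[museum])
    classification_table = None
    if config.run_sex_assignment:
        classification_table = assign_unknown_sex(scaled_all, metadata, seed=config.seed)
    report = RunReport(
        classification_table=classification_table,
        quartet_table=quartet_table,
        summary=summary,
        outlier_tables=outlier_tables,
        convergence_table=convergence_table,
        pca_summary=pca,
        traits=traits,
        metadata=metadata,
        provenance={"seed": config.seed, "t_variant": config.t_variant,
                    "scaling_population": config.scaling_population,
                    "n_perm": config.n_perm, "n_boot": config.n_boot,
                    "alpha": config.alpha, "min_n": config.min_n},
    )
    if config.outdir is not None:
        write_report(report, config.outdir)
    return report


def assign_unknown_sex(
    scaled: pd.DataFrame,
    metadata: pd.DataFrame,
    threshold: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame | None:
    """Assign sex to unknown-sex specimens from pelvic shape variables.

    Trains the discriminant on specimens with unambiguous sex; only
    posteriors >= ``threshold`` are accepted. Returns None when the
    training set lacks both sexes or nothing is unknown.
    """
    pelvic_cols = [c for c in scaled.columns if c.startswith("shape_pel_")]
    known = metadata.index[metadata["sex"].isin(["male", "female"])]
    unknown = metadata.index[metadata["sex"] == "unknown"]
    if len(unknown) == 0 or metadata.loc[known, "sex"].nunique() < 2:
        return None
    model = _classify.lda_fit(scaled.loc[known, pelvic_cols], metadata.loc[known, "sex"])
    results = _classify.lda_assign(model, scaled.loc[unknown, pelvic_cols], threshold=threshold)
    return pd.DataFrame(
        [{"specimen_id": r.specimen_id, "predicted": r.predicted,
          "posterior": r.posterior, "accepted": r.accepted} for r in results]
    )


def write_report(report: RunReport, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.quartet_table.to_csv(out / "quartets.csv", index=False)
    if report.convergence_table is not None:
        report.convergence_table.to_csv(out / "convergence.csv", index=False)
    if report.classification_table is not None:
        report.classification_table.to_csv(out / "sex_assignment.csv", index=False)
    for key, table in report.outlier_tables.items():
        safe = key.replace("/", "-")
        table.to_csv(out / f"outliers_{safe}.csv", index=False)
    with open(out / "summary.txt", "w") as fh:
        fh.write("pipeline run summary\n")
        for k, v in report.provenance.items():
            fh.write(f"  {k}: {v}\n")
        for k, v in report.summary.items():
            fh.write(f"{k}: {v}\n")
        vf = report.pca_summary.variance_fractions
        fh.write(f"PC1_variance_pct: {100 * vf[0]:.2f}\n")
        fh.write(f"PC2_variance_pct: {100 * vf[1]:.2f}\n")
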