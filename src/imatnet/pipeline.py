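"""End-to-end orchestration: simulate -> regress -> cluster -> classify -> intervene.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so stages can be executed and tested in isolation. A run manifest
(JSON) records the configuration, the per-stage child seeds and a SHA-256
checksum of every data output; re-running with the same config and seed
reproduces identical checksums (provenance sidecars, which carry wall-clock
timestamps, are excluded from checksumming).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from . import __version__
from .datatypes import align
from .errors import InvalidParameterError, PipelineStageError
from .simulate import CohortSpec, GeneSpec, InterventionSpec
from . import clustering as clustmod
from . import intervention as intmod
from . import knn as knnmod
from . import regression as regmod

log = logging.getLogger("imatnet.pipeline")

STAGES = ("simulate", "regress", "cluster", "classify", "intervene")


@dataclass
class StageParams:
    n_top: int = 59
    k_clusters: int = 3
    cluster_method: str = "kmeans"
    feature_space: str = "beta"
    k_neighbours: int = 3
    alpha: float = 0.05
    correlation: str = "pearson"
    calibrator: str = "pre-group-mean"

    def validate(self) -> list[str]:
        errors = []
        if self.n_top < 1:
            errors.append(f"n_top must be >= 1, got {self.n_top}")
        if self.k_clusters < 1:
            errors.append(f"k_clusters must be >= 1, got {self.k_clusters}")
        if self.cluster_method not in ("kmeans", "hierarchical"):
            errors.append(f"unknown cluster_method '{self.cluster_method}'")
        if self.feature_space not in ("beta", "expression"):
            errors.append(f"unknown feature_space '{self.feature_space}'")
        if self.k_neighbours < 1:
            errors.append(f"k_neighbours must be >= 1, got {self.k_neighbours}")
        if not 0 < self.alpha < 1:
            errors.append(f"alpha must be in (0, 1), got {self.alpha}")
        if self.correlation not in ("pearson", "spearman"):
            errors.append(f"unknown correlation '{self.correlation}'")
        if self.calibrator not in ("pre-group-mean", "named-sample"):
            errors.append(f"unknown calibrator '{self.calibrator}'")
        return errors


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/default"
    stages: tuple = STAGES
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    gene_spec: GeneSpec = field(default_factory=GeneSpec)
    intervention_spec: InterventionSpec = field(default_factory=InterventionSpec)
    params: StageParams = field(default_factory=StageParams)

    def validate(self) -> list[str]:
        errors = self.params.validate()
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            errors.append(f"unknown stage(s): {unknown}")
        for spec in (self.cohort_spec, self.gene_spec, self.intervention_spec):
            try:
                spec.validate()
            except InvalidParameterError as exc:
                errors.append(str(exc))
        return errors

    def stage_seeds(self) -> dict:
        """Deterministic per-stage child seeds from the root seed."""
        state = np.random.SeedSequence(self.seed).generate_state(4)
        names = ("cohort", "genes", "intervention", "clustering")
        return {n: int(s & 0x7FFFFFFF) for n, s in zip(names, state)}


_TOP_KEYS = {"seed", "outdir", "stages", "cohort", "genes", "intervention", "params"}


def config_from_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from a parsed config mapping, collecting all errors."""
    errors = [f"unknown config key '{k}'" for k in raw if k not in _TOP_KEYS]
    cfg = RunConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "outdir" in raw:
        cfg.outdir = str(raw["outdir"])
    if "stages" in raw:
        cfg.stages = tuple(raw["stages"])
    try:
        if "cohort" in raw:
            cfg.cohort_spec = CohortSpec.from_dict(raw["cohort"]) \
                if "groups" in raw["cohort"] else _update(CohortSpec(), raw["cohort"])
        if "genes" in raw:
            cfg.gene_spec = GeneSpec.from_dict(raw["genes"])
        if "intervention" in raw:
            cfg.intervention_spec = InterventionSpec.from_dict(raw["intervention"])
        if "params" in raw:
            for k, v in raw["params"].items():
                if not hasattr(cfg.params, k):
                    errors.append(f"unknown params key '{k}'")
                else:
                    setattr(cfg.params, k, v)
    except InvalidParameterError as exc:
        errors.append(str(exc))
    errors.extend(cfg.validate())
    if errors:
        raise InvalidParameterError("; ".join(errors))
    return cfg


def _update(spec, d):
    for k, v in d.items():
        if not hasattr(spec, k):
            raise InvalidParameterError(f"unknown cohort key '{k}'")
        setattr(spec, k, v)
    return spec


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; raises with every violation listed."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"{path}: config must be a mapping")
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, outdir: Path, seeds: dict) -> list[Path]:
    from .simulate import generate_cohort, generate_expression, generate_intervention_cohort

    cfg.cohort_spec.seed = seeds["cohort"]
    cfg.gene_spec.seed = seeds["genes"]
    cfg.intervention_spec.seed = seeds["intervention"]

    cohort = generate_cohort(cfg.cohort_spec)
    muscle, imat, truth = generate_expression(cohort, cfg.gene_spec)
    iclin, ct, itruth = generate_intervention_cohort(cfg.intervention_spec)

    outputs = {
        "clinical.csv": lambda p: iomod.write_clinical_table(cohort, p, seed=cfg.seed),
        "expression_muscle.tsv": lambda p: iomod.write_expression_matrix(muscle, p, seed=cfg.seed),
        "expression_imat.tsv": lambda p: iomod.write_expression_matrix(imat, p, seed=cfg.seed),
        "truth_genes.csv": lambda p: iomod.write_table(truth, p, seed=cfg.seed),
        "intervention_clinical.csv": lambda p: iomod.write_clinical_table(iclin, p, seed=cfg.seed),
        "intervention_ct.csv": lambda p: iomod.write_table(ct, p, seed=cfg.seed),
        "truth_intervention.csv": lambda p: iomod.write_table(itruth, p, seed=cfg.seed),
    }
    written = []
    for name, writer in outputs.items():
        path = outdir / name
        writer(path)
        written.append(path)
    return written


def _stage_regress(cfg: RunConfig, outdir: Path, seeds: dict) -> list[Path]:
    clin = iomod.read_clinical_table(outdir / "clinical.csv")
    muscle = iomod.read_expression_matrix(outdir / "expression_muscle.tsv", "muscle")
    imat = iomod.read_expression_matrix(outdir / "expression_imat.tsv", "imat")
    muscle, pheno = align(muscle, clin)
    imat, _ = align(imat, clin)
    fits = regmod.fit_all_genes(muscle, imat, pheno)
    ranking = regmod.rank_and_select(fits, n_top=cfg.params.n_top)
    path = outdir / "gene_fits.csv"
    iomod.write_table(regmod.fits_to_frame(fits, ranking), path, seed=cfg.seed)
    return [path]


def _stage_cluster(cfg: RunConfig, outdir: Path, seeds: dict) -> list[Path]:
    fits_frame = pd.read_csv(outdir / "gene_fits.csv")
    selected = fits_frame[fits_frame["selected"]]
    scores = selected.set_index("gene_id")["score"]
    if cfg.params.feature_space == "beta":
        features = selected.set_index("gene_id")[list(regmod.BETA_NAMES)]
    else:
        muscle = iomod.read_expression_matrix(outdir / "expression_muscle.tsv", "muscle")
        imat = iomod.read_expression_matrix(outdir / "expression_imat.tsv", "imat")
        features = clustmod.expression_features(muscle, imat, selected["gene_id"])
    assignment = clustmod.cluster_genes(
        features, k=cfg.params.k_clusters, method=cfg.params.cluster_method,
        scores=scores, seed=seeds["clustering"],
        feature_space=cfg.params.feature_space)

    fits = [
        regmod.GeneModelFit(
            gene_id=row.gene_id,
            beta=np.array([[row.beta_mg, row.beta_mf], [row.beta_ig, row.beta_if]]),
            resid_cov=np.eye(2), resid_cov_det=1.0,
            loglik_full=row.loglik_full, loglik_null=row.loglik_null,
            n_used=int(row.n_used),
        )
        for row in selected.itertuples()
    ]
    summary = clustmod.summarize_cluster_patterns(assignment, fits)

    out_assign = outdir / "cluster_assignment.csv"
    assign_frame = assignment.labels.rename("cluster").rename_axis("gene_id").reset_index()
    tag_by_cluster = summary.table.set_index("cluster")["pattern_tag"]
    assign_frame["tag"] = assign_frame["cluster"].map(tag_by_cluster)
    iomod.write_table(assign_frame, out_assign, seed=cfg.seed)
    out_summary = outdir / "cluster_summary.csv"
    iomod.write_table(summary.table, out_summary, seed=cfg.seed)
    return [out_assign, out_summary]


def _stage_classify(cfg: RunConfig, outdir: Path, seeds: dict) -> list[Path]:
    clin = iomod.read_clinical_table(outdir / "clinical.csv")
    muscle = iomod.read_expression_matrix(outdir / "expression_muscle.tsv", "muscle")
    imat = iomod.read_expression_matrix(outdir / "expression_imat.tsv", "imat")
    assign_frame = pd.read_csv(outdir / "cluster_assignment.csv")
    assignment = clustmod.GeneClusterAssignment(
        labels=assign_frame.set_index("gene_id")["cluster"],
        k=int(assign_frame["cluster"].nunique()),
        method=cfg.params.cluster_method,
        feature_space=cfg.params.feature_space, seed=seeds["clustering"])
    spec = knnmod.NetworkSpec(k=cfg.params.k_neighbours)
    networks, per_cluster, per_tissue, overall, report = knnmod.run_network_stage(
        muscle, imat, assignment, clin, spec)

    written = []
    for (tissue, cluster), net in sorted(networks.items()):
        path = outdir / f"network_{tissue}_c{cluster}.csv"
        iomod.write_table(net.edge_frame(), path, seed=cfg.seed)
        written.append(path)
    scores_frame = pd.concat(
        [sc.as_frame() for sc in per_cluster.values()]
        + [sc.as_frame() for sc in per_tissue.values()]
        + [overall.as_frame()],
        ignore_index=True)
    path = outdir / "classification_scores.csv"
    iomod.write_table(scores_frame, path, seed=cfg.seed)
    written.append(path)
    path = outdir / "discordance_report.csv"
    iomod.write_table(report, path, seed=cfg.seed)
    written.append(path)
    return written


def _stage_intervene(cfg: RunConfig, outdir: Path, seeds: dict) -> list[Path]:
    clin = iomod.read_clinical_table(outdir / "intervention_clinical.csv")
    ct = iomod.read_ct_table(outdir / "intervention_ct.csv")
    changes = intmod.change_test_table(clin)
    rel = intmod.relative_expression(
        ct, reference_gene=cfg.intervention_spec.reference_gene,
        calibrator=cfg.params.calibrator)
    de = intmod.differential_expression_table(rel)
    screen = intmod.correlation_screen(
        intmod.baseline_matrix(rel), intmod.delta_matrix(clin),
        intmod.ScreenConfig(alpha=cfg.params.alpha, method=cfg.params.correlation))
    written = []
    for name, frame in (("change_tests.csv", changes),
                        ("relative_expression.csv", rel),
                        ("differential_expression.csv", de),
                        ("correlation_screen.csv", screen)):
        path = outdir / name
        iomod.write_table(frame, path, seed=cfg.seed)
        written.append(path)
    return written


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "regress": _stage_regress,
    "cluster": _stage_cluster,
    "classify": _stage_classify,
    "intervene": _stage_intervene,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    errors = config.validate()
    if errors:
        raise InvalidParameterError("; ".join(errors))
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()

    manifest = {
        "package": "imatnet",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "params": vars(config.params),
        "stages": [],
        "outputs": {},
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage '%s'", stage)
        try:
            written = _STAGE_FUNCS[stage](config, outdir, seeds)
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc
        manifest["stages"].append(stage)
        for path in written:
            manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
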