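"""End-to-end reproducible runs: simulate -> segment -> gate -> enumerate ->
cut-offs -> survival models, driven by a single config.

Every run writes a manifest recording the config hash, the global seed and
every artifact produced, and is byte-reproducible: the same config yields the
same outputs.
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

import ctcev
from ctcev.simulate.images import ImageSimParams, generate_cartridge
from ctcev.simulate.cohort import CohortSimParams, generate_cohort
from ctcev.pipeline import SegmentationConfig, extract_objects
from ctcev.gating import GateDefinition, ctc_gate, tdev_gate, enumerate_cartridge, compare_counts
from ctcev.biomarkers import describe, mann_whitney, correlate, roc_cutoff, BiomarkerError
from ctcev import survival as surv

log = logging.getLogger("ctcev.workflow")


class ConfigError(ValueError):
    """Invalid or unresolvable run configuration."""


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    All analysis thresholds live here: gate files (or None for the built-in
    gates), the ROC marker lists, the truncation time tau (months), the
    stepwise entry/exit p-values and the bootstrap replicate count.
    """

    seed: int = 0
    # image stage: simulate `n_cartridges` stacks with planted CTC/tdEV
    # counts drawn from `ctc_count_range` / `tdev_count_range`
    n_cartridges: int = 4
    image_params: dict = field(default_factory=dict)
    ctc_count_range: tuple = (0, 30)
    tdev_count_range: tuple = (50, 500)
    gates_file: str | None = None
    segmentation: dict = field(default_factory=dict)
    # cohort stage
    cohort_params: dict = field(default_factory=dict)
    cohort_file: str | None = None
    # ROC stage
    count_markers: tuple = ("ctc", "tdev")
    per_dataset_markers: tuple = ("ck18", "cck18")
    # survival stage
    tau: float = 24.0
    frailty: bool = True
    p_in: float = 0.05
    p_out: float = 0.10
    bootstrap_reps: int = 1000
    candidates: tuple = (
        "ctc",
        "tdev",
        "ck18",
        "cck18",
        "psa",
        "ldh",
        "alp",
        "albumin",
        "hemoglobin",
        "age",
    )
    clinical_covariates: tuple = ("ldh", "albumin", "hemoglobin")
    marker_covariate: str = "tdev"

    def validate(self) -> None:
        if self.tau <= 0:
            raise ConfigError("tau must be > 0")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be >= 1")
        if self.n_cartridges < 0:
            raise ConfigError("n_cartridges must be >= 0")
        for name in ("gates_file", "cohort_file"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} does not exist: {path}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def demo_config(seed: int = 20) -> RunConfig:
    """The bundled demonstration: two datasets with a shared frailty, a
    prognostic tdEV signal, CTC counts correlated ~0.8 with tdEV on the
    latent scale, and a null ccCK18."""
    return RunConfig(
        seed=seed,
        n_cartridges=4,
        image_params={"frames": 16, "frame_shape": (256, 256)},
        cohort_params={
            "n_patients": {"retrospective": 200, "prospective": 200},
            "ctc_tdev_corr": 0.8,
            "coefficients": {
                "tdev": 0.45,
                "ldh": 0.8,
                "albumin": -0.5,
                "hemoglobin": -0.12,
            },
            "frailty_variance": 0.15,
            "censoring_rate": 0.2,
        },
        bootstrap_reps=1000,
    )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _load_gates(config: RunConfig):
    if config.gates_file is None:
        return ctc_gate(), tdev_gate()
    text = Path(config.gates_file).read_text()
    raw = json.loads(text)
    gates = [GateDefinition.from_json(json.dumps(g)) for g in raw]
    by_name = {g.name: g for g in gates}
    try:
        return by_name["ctc"], by_name["tdev"]
    except KeyError as exc:
        raise ConfigError(f"gates file must define 'ctc' and 'tdev' gates: {exc}") from exc


def _stage_images(config: RunConfig, outdir: Path, manifest: dict) -> None:
    ss = np.random.SeedSequence([config.seed, 1])
    seeds = ss.generate_state(config.n_cartridges)
    rng = np.random.default_rng(ss.spawn(1)[0])
    gate_c, gate_t = _load_gates(config)
    seg = SegmentationConfig(**config.segmentation)
    rows = []
    for k in range(config.n_cartridges):
        params = ImageSimParams(
            n_ctc=int(rng.integers(config.ctc_count_range[0], config.ctc_count_range[1] + 1)),
            n_tdev=int(rng.integers(config.tdev_count_range[0], config.tdev_count_range[1] + 1)),
            seed=int(seeds[k] % (2**31)),
            **config.image_params,
        )
        stack, truth = generate_cartridge(params, cartridge_id=f"cartridge{k:02d}")
        events = extract_objects(stack, seg)
        res = enumerate_cartridge(events, gate_c, gate_t, cartridge_id=stack.cartridge_id)
        log.info(
            "cartridge %s: %d frames -> %d objects -> %d CTC, %d tdEV (planted %d, %d)",
            stack.cartridge_id,
            stack.n_frames,
            res.n_objects_total,
            res.n_ctc,
            res.n_tdev,
            params.n_ctc,
            params.n_tdev,
        )
        rows.append(
            {
                "cartridge_id": stack.cartridge_id,
                "n_frames": stack.n_frames,
                "n_objects_total": res.n_objects_total,
                "n_ctc": res.n_ctc,
                "n_tdev": res.n_tdev,
                "true_ctc": params.n_ctc,
                "true_tdev": params.n_tdev,
            }
        )
    enum_df = pd.DataFrame(rows)
    enum_path = outdir / "enumeration.csv"
    enum_df.to_csv(enum_path, index=False)
    manifest["outputs"].append(enum_path.name)
    if len(enum_df) >= 3 and enum_df["true_ctc"].var() > 0:
        slope, intercept, r2 = compare_counts(enum_df["true_ctc"], enum_df["n_ctc"])
        manifest["stages"]["enumeration"] = {
            "n_cartridges": int(len(enum_df)),
            "ctc_regression": {"slope": slope, "intercept": intercept, "r_squared": r2},
        }
    else:
        manifest["stages"]["enumeration"] = {"n_cartridges": int(len(enum_df))}


def _stage_cohort(config: RunConfig, outdir: Path, manifest: dict) -> pd.DataFrame:
    if config.cohort_file is not None:
        cohort = pd.read_csv(config.cohort_file)
    else:
        params = CohortSimParams(seed=config.seed + 2, **config.cohort_params)
        cohort = generate_cohort(params)
    path = outdir / "cohort.csv"
    cohort.to_csv(path, index=False)
    manifest["outputs"].append(path.name)
    manifest["stages"]["cohort"] = {
        "n_patients": int(len(cohort)),
        "n_events": int(cohort["event"].sum()),
        "datasets": {k: int(v) for k, v in cohort["dataset"].value_counts().items()},
    }
    return cohort


def _stage_descriptives(config: RunConfig, cohort: pd.DataFrame, outdir: Path, manifest: dict) -> None:
    markers = [m for m in (*config.count_markers, *config.per_dataset_markers) if m in cohort]
    rows = []
    for marker in markers:
        for label, sub in cohort.groupby("dataset"):
            s = describe(sub[marker])
            rows.append({"marker": marker, "dataset": label, **s.to_dict()})
    pd.DataFrame(rows).to_csv(outdir / "descriptives.csv", index=False)
    manifest["outputs"].append("descriptives.csv")

    tests = {}
    labels = sorted(cohort["dataset"].unique())
    if len(labels) == 2:
        a, b = labels
        for marker in markers:
            u, p = mann_whitney(
                cohort.loc[cohort["dataset"] == a, marker],
                cohort.loc[cohort["dataset"] == b, marker],
            )
            tests[marker] = {"U": u, "p": p}
    if {"ctc", "tdev"} <= set(cohort.columns):
        rho, p = correlate(cohort["ctc"], cohort["tdev"], method="spearman")
        tests["ctc_vs_tdev_spearman"] = {"rho": rho, "p": p}
    _write_json(outdir / "group_tests.json", tests)
    manifest["outputs"].append("group_tests.json")


def _stage_cutoffs(config: RunConfig, cohort: pd.DataFrame, outdir: Path, manifest: dict) -> dict:
    cutoffs = {}
    report = {}
    for marker in config.count_markers:
        if marker not in cohort:
            continue
        roc = roc_cutoff(cohort[marker], cohort["os_months"], cohort["event"])
        roc.to_frame().to_csv(outdir / f"roc_{marker}.csv", index=False)
        manifest["outputs"].append(f"roc_{marker}.csv")
        cutoffs[marker] = {"__all__": roc.cutoff}
        report[marker] = roc.to_json_dict()
    for marker in config.per_dataset_markers:
        if marker not in cohort:
            continue
        cutoffs[marker] = {}
        report[marker] = {}
        for label, sub in cohort.groupby("dataset"):
            try:
                roc = roc_cutoff(sub[marker], sub["os_months"], sub["event"])
            except BiomarkerError as exc:
                report[marker][label] = {"error": str(exc)}
                continue
            roc.to_frame().to_csv(outdir / f"roc_{marker}_{label}.csv", index=False)
            manifest["outputs"].append(f"roc_{marker}_{label}.csv")
            cutoffs[marker][label] = roc.cutoff
            report[marker][label] = roc.to_json_dict()
    _write_json(outdir / "cutoffs.json", report)
    manifest["outputs"].append("cutoffs.json")
    manifest["stages"]["cutoffs"] = cutoffs
    return cutoffs


def _dichotomize(cohort: pd.DataFrame, marker: str, cutoffs: dict) -> np.ndarray:
    """Unfavorable = value >= cut-off (per dataset when per-dataset cut-offs
    were determined)."""
    rule = cutoffs[marker]
    if "__all__" in rule:
        return (cohort[marker] >= rule["__all__"]).to_numpy()
    out = np.zeros(len(cohort), dtype=bool)
    for label, cut in rule.items():
        mask = (cohort["dataset"] == label).to_numpy()
        out |= mask & (cohort[marker] >= cut).to_numpy()
    return out


def _stage_km(config: RunConfig, cohort: pd.DataFrame, cutoffs: dict, outdir: Path, manifest: dict) -> None:
    km_report = {}
    for marker, rule in cutoffs.items():
        if not rule:
            km_report[marker] = {"error": "no cut-off available"}
            continue
        unfav = _dichotomize(cohort, marker, cutoffs)
        if unfav.sum() == 0 or unfav.sum() == len(cohort):
            km_report[marker] = {"error": "degenerate dichotomization"}
            continue
        t = cohort["os_months"].to_numpy(dtype=float)
        e = cohort["event"].to_numpy(dtype=int)
        curves = {}
        for name, mask in (("favorable", ~unfav), ("unfavorable", unfav)):
            km = surv.km_fit(t[mask], e[mask])
            km.to_frame().to_csv(outdir / f"km_{marker}_{name}.csv", index=False)
            manifest["outputs"].append(f"km_{marker}_{name}.csv")
            curves[name] = {
                "n": km.n,
                "median_os_months": None if not np.isfinite(km.median) else km.median,
            }
        chi2, p = surv.logrank((t[~unfav], e[~unfav]), (t[unfav], e[unfav]))
        km_report[marker] = {"groups": curves, "logrank_chi2": chi2, "logrank_p": p}
    _write_json(outdir / "km_logrank.json", km_report)
    manifest["outputs"].append("km_logrank.json")
    manifest["stages"]["km"] = {m: r.get("logrank_p") for m, r in km_report.items() if "logrank_p" in r}


def _stage_cox(config: RunConfig, cohort: pd.DataFrame, outdir: Path, manifest: dict):
    table = surv.transform_covariates(cohort)
    frailty_col = "dataset" if config.frailty else None
    candidates = [c for c in config.candidates if c in table.columns]

    uni = {}
    for cov in candidates:
        try:
            fit = surv.cox_fit(table, [cov], frailty_col=frailty_col)
            uni[cov] = fit.to_json_dict()
        except (surv.SurvivalError, surv.ConvergenceError) as exc:
            uni[cov] = {"error": str(exc)}
    _write_json(outdir / "cox_univariable.json", uni)
    manifest["outputs"].append("cox_univariable.json")

    final, trace = surv.forward_stepwise(
        table,
        candidates,
        p_in=config.p_in,
        p_out=config.p_out,
        frailty_col=frailty_col,
    )
    _write_json(
        outdir / "cox_stepwise.json",
        {"final_model": final.to_json_dict(), "trace": trace},
    )
    manifest["outputs"].append("cox_stepwise.json")
    manifest["stages"]["stepwise"] = {
        "selected": list(final.covariates),
        "frailty_variance": final.frailty_variance,
    }
    return table, final


def _stage_cindex(config: RunConfig, table: pd.DataFrame, outdir: Path, manifest: dict) -> None:
    clinical = [c for c in config.clinical_covariates if c in table.columns]
    marker_model = [config.marker_covariate] + clinical
    report = surv.bootstrap_c_delta(
        table,
        covariates_a=marker_model,
        covariates_b=clinical,
        tau=config.tau,
        reps=config.bootstrap_reps,
        seed=config.seed + 7,
        frailty_col="dataset" if config.frailty else None,
        bootstrap_frailty=False,
    )
    _write_json(outdir / "cindex_comparison.json", report.to_json_dict())
    manifest["outputs"].append("cindex_comparison.json")
    manifest["stages"]["cindex"] = {
        "model_with_marker": report.c_a,
        "clinical_only": report.c_b,
        "delta": report.delta,
    }


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage; returns the manifest (also written to
    ``outdir/manifest.json``).

    Any stage failure aborts the run with the stage name attached to the
    raised exception.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config": config_dict,
        "config_sha256": config_hash,
        "seed": config.seed,
        "version": ctcev.__version__,
        "outputs": [],
        "stages": {},
    }
    stages = [
        ("images", lambda: _stage_images(config, outdir, manifest)),
        ("cohort", lambda: _stage_cohort(config, outdir, manifest)),
    ]
    cohort = None
    for name, fn in stages:
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        if name == "cohort":
            cohort = out
    try:
        _stage_descriptives(config, cohort, outdir, manifest)
        cutoffs = _stage_cutoffs(config, cohort, outdir, manifest)
        _stage_km(config, cohort, cutoffs, outdir, manifest)
        table, final = _stage_cox(config, cohort, outdir, manifest)
        _stage_cindex(config, table, outdir, manifest)
    except Exception as exc:
        stage = getattr(exc, "_ctcev_stage", "analysis")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    _write_json(outdir / "manifest.json", manifest)
    return manifest
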