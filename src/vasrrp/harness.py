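"""Replication engine for the two format-comparison simulation studies.

Study 1 (VAS-RRP vs Likert): per replication, draw n respondents from the
CTCU generating model, score them as VAS-RRP, and draw a matched CT-model
dataset that is discretized at each configured cut-point set to give the
Likert conditions.  Cronbach's alpha is computed per trait, the CTCU
template is fitted to the VAS-RRP data and the CT template to each Likert
dataset, and fit indices, composite reliabilities (from fitted parameters)
and parameter estimates are aggregated into mean/SE tables across
replications.

Study 2 (VAS-RRP vs ranking): one recorded-seed dataset is scored as
VAS-RRP and as within-testlet ranks; both are factored by principal
components with promax rotation, and structure tables, component
correlations, reliabilities and PVE are reported side by side.

The reported "SE" of every cell is the standard deviation of the statistic
across replications (the dispersion of the replication distribution, not
the SD divided by the square root of the replication count); the manifest
records this convention.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cfa import fit_with_indices
from .efa import align_columns, extract_components, rotate_oblique, structure_table
from .factor_model import (
    FactorModelSpec,
    make_4l4i_spec,
    make_4l8i_spec,
)
from .reliability import composite_reliability, cronbach_alpha
from .synthetic_data import (
    generate_dataset,
    to_likert,
    to_ranking,
    to_vasrrp,
)

__all__ = [
    "SimulationConfig",
    "AggregateTable",
    "SimulationResults",
    "run_simulation",
    "run_ranking_comparison",
    "parameter_recovery_summary",
    "write_outputs",
    "cli_main",
]

logger = logging.getLogger("vasrrp")

#: Seed offsets keeping every derived stream reproducible from the master
#: seed (all stay far below 2**31 for small master seeds).
CT_STREAM_OFFSET = 500_000
RETRY_STREAM_OFFSET = 1_000_000
SIM2_STREAM_OFFSET = 777_777

#: Abort a run when more than this share of replications fails.
MAX_FAILURE_FRACTION = 0.20

DEFAULT_CUT_POINT_SETS = (
    (-2.0, 2.0),
    (-1.0, 1.0),
    (-3.0, -1.0, 1.0, 3.0),
    (-1.5, -0.5, 0.5, 1.5),
)


@dataclass
class SimulationConfig:
    """Run description: which generating model, which response formats, and
    how many replications at which sample size."""

    model: str = "4L4I"  # "4L4I" | "4L8I" | path to a spec YAML
    n: int = 500
    replications: int = 500
    seed: int = 12345
    vasrrp: bool = True
    likert_cut_points: tuple = DEFAULT_CUT_POINT_SETS
    fit_models: bool = True
    sim2: bool = True
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("need at least one replication")
        self.likert_cut_points = tuple(
            tuple(float(c) for c in cuts) for cuts in self.likert_cut_points
        )
        for cuts in self.likert_cut_points:
            if len(cuts) == 0 or any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"cut points must be strictly ascending: {cuts}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n": self.n,
            "replications": self.replications,
            "seed": self.seed,
            "vasrrp": self.vasrrp,
            "likert_cut_points": [list(c) for c in self.likert_cut_points],
            "fit_models": self.fit_models,
            "sim2": self.sim2,
            "outdir": self.outdir,
        }

    def resolve_spec(self) -> FactorModelSpec:
        """The CTCU generating spec named by ``model``."""
        if self.model == "4L4I":
            return make_4l4i_spec("CTCU")
        if self.model == "4L8I":
            return make_4l8i_spec("CTCU")
        return FactorModelSpec.from_yaml(Path(self.model).read_text())


@dataclass
class AggregateTable:
    """Mean/SE cells over replications in tidy form."""

    table: pd.DataFrame
    replications: int
    dropped: int = 0


@dataclass
class SimulationResults:
    tables: dict = field(default_factory=dict)  # name -> AggregateTable
    manifest: dict = field(default_factory=dict)
    log_lines: list = field(default_factory=list)


def _cut_label(cuts) -> str:
    def fmt(c):
        return f"{c:g}"

    return "{" + ",".join(fmt(c) for c in cuts) + "}"


def _parameter_names(spec: FactorModelSpec, template: str) -> list[str]:
    names = [f"lambda_{i + 1}" for i in range(spec.n_items)]
    L = spec.n_latents
    names += [f"phi_{a + 1}_{b + 1}" for a in range(L) for b in range(a + 1, L)]
    names += [f"theta_var_{i + 1}" for i in range(spec.n_items)]
    if template == "CTCU":
        for t in range(spec.n_testlets):
            names += [
                f"testlet{t + 1}_rho_{a + 1}_{b + 1}"
                for a in range(L)
                for b in range(a + 1, L)
            ]
    return names


def _parameter_vector(fit_or_spec, template: str) -> np.ndarray:
    """Flatten loadings / latent correlations / residual variances (and
    CTCU residual correlations) in the order of :func:`_parameter_names`."""
    obj = fit_or_spec
    L = obj.latent_corr.shape[0]
    iu = [(a, b) for a in range(L) for b in range(a + 1, L)]
    parts = [np.asarray(obj.loadings, float)]
    parts.append(np.array([obj.latent_corr[a][b] for a, b in iu]))
    parts.append(np.asarray(obj.residual_vars, float))
    if template == "CTCU":
        tcorr = obj.testlet_residual_corr
        for t in range(len(tcorr)):
            parts.append(np.array([tcorr[t][a][b] for a, b in iu]))
    return np.concatenate(parts)


def parameter_recovery_summary(fits, truth: FactorModelSpec) -> pd.DataFrame:
    """Replication mean, SD and bias for every free parameter.

    All fits must share a template; CT fits carry no residual-correlation
    block, so none is reported for them.
    """
    if not fits:
        raise ValueError("no fits to summarize")
    template = fits[0].template
    if any(f.template != template for f in fits):
        raise ValueError("fits mix templates")
    names = _parameter_names(truth, template)
    est = np.stack([_parameter_vector(f, template) for f in fits])
    true_vec = _parameter_vector(truth.with_mode(template), template)
    mean = est.mean(axis=0)
    sd = est.std(axis=0, ddof=1) if len(fits) > 1 else np.full(est.shape[1], np.nan)
    return pd.DataFrame(
        {
            "parameter": names,
            "true": true_vec,
            "mean": mean,
            "se": sd,
            "bias": mean - true_vec,
        }
    )


def _replication(spec_ctcu, spec_ct, config, seed):
    """One replication: returns per-condition statistics, or raises
    RuntimeError on a non-converged fit."""
    out = {"alpha": {}, "composite": {}, "fits": {}, "clip": None}
    n = config.n
    if config.vasrrp:
        data = generate_dataset(spec_ctcu, n, seed)
        out["clip"] = data.clip_fraction
        vas = to_vasrrp(data)
        out["alpha"]["vasrrp"] = [
            cronbach_alpha(vas.values[:, spec_ctcu.items_of_latent(l)])
            for l in range(spec_ctcu.n_latents)
        ]
        if config.fit_models:
            # affine-equivalent to the VAS-RRP scores; keeps estimates in
            # the generating metric
            S = np.cov(data.values, rowvar=False)
            fit = fit_with_indices(S, n, "CTCU", spec_ctcu)
            if not fit.converged:
                raise RuntimeError("CTCU fit did not converge")
            out["fits"]["vasrrp"] = fit
            out["composite"]["vasrrp"] = [
                composite_reliability(
                    fit.loadings[spec_ctcu.items_of_latent(l)],
                    fit.residual_vars[spec_ctcu.items_of_latent(l)],
                )
                for l in range(spec_ctcu.n_latents)
            ]
    if config.likert_cut_points:
        # Likert conditions discretize data generated without context
        # effects (the CT model)
        data_ct = generate_dataset(spec_ct, n, seed + CT_STREAM_OFFSET)
        for cuts in config.likert_cut_points:
            label = _cut_label(cuts)
            lik = to_likert(data_ct, cuts)
            out["alpha"][label] = [
                cronbach_alpha(lik.values[:, spec_ct.items_of_latent(l)])
                for l in range(spec_ct.n_latents)
            ]
            if config.fit_models:
                S = np.cov(lik.values.astype(float), rowvar=False)
                fit = fit_with_indices(S, n, "CT", spec_ct)
                if not fit.converged:
                    raise RuntimeError(f"CT fit did not converge ({label})")
                out["fits"][label] = fit
                out["composite"][label] = [
                    composite_reliability(
                        fit.loadings[spec_ct.items_of_latent(l)],
                        fit.residual_vars[spec_ct.items_of_latent(l)],
                    )
                    for l in range(spec_ct.n_latents)
                ]
    return out


def run_simulation(config: SimulationConfig) -> SimulationResults:
    """Run Study 1 end to end and aggregate the mean/SE tables.

    Replication r uses seed ``config.seed + r``; failed replications are
    regenerated from a retry stream and counted, and the run aborts if more
    than 20% of replications fail.
    """
    spec_ctcu = config.resolve_spec()
    spec_ct = spec_ctcu.with_mode("CT")
    reps, results, dropped = config.replications, [], 0
    retry = 0
    max_failures = max(1, int(MAX_FAILURE_FRACTION * reps))
    r = 0
    while len(results) < reps:
        if r < reps:
            seed = config.seed + r
        else:
            seed = config.seed + RETRY_STREAM_OFFSET + retry
            retry += 1
        r += 1
        try:
            results.append(_replication(spec_ctcu, spec_ct, config, seed))
        except RuntimeError as exc:
            dropped += 1
            logger.warning("replication with seed %d dropped: %s", seed, exc)
            if dropped > max_failures:
                raise RuntimeError(
                    f"{dropped} of {r} replications failed; aborting"
                ) from exc

    L = spec_ctcu.n_latents
    scales = list(results[0]["alpha"].keys())

    def scale_kind(s):
        return "VAS-RRP" if s == "vasrrp" else "Likert"

    # Table 1 analog: Cronbach's alpha
    rows = []
    for s in scales:
        arr = np.array([rep["alpha"][s] for rep in results])
        for l in range(L):
            rows.append(
                {
                    "model": spec_ctcu.name,
                    "scale": scale_kind(s),
                    "cut_points": "" if s == "vasrrp" else s,
                    "latent": l + 1,
                    "statistic": "cronbach_alpha",
                    "mean": arr[:, l].mean(),
                    "se": arr[:, l].std(ddof=1) if reps > 1 else np.nan,
                    "reps": reps,
                }
            )
    tables = {"table1_alpha": AggregateTable(pd.DataFrame(rows), reps, dropped)}

    if config.fit_models:
        # Table 2 analog: fit indices
        rows = []
        for s in scales:
            fits = [rep["fits"][s] for rep in results]
            stats = {
                "rmsea": [f.indices.rmsea for f in fits],
                "srmr": [f.indices.srmr for f in fits],
                "cfi": [f.indices.cfi for f in fits],
                "tli": [f.indices.tli for f in fits],
                "chi_square": [f.chi_square for f in fits],
            }
            for stat, vals in stats.items():
                vals = np.asarray(vals)
                rows.append(
                    {
                        "model": spec_ctcu.name,
                        "scale": scale_kind(s),
                        "cut_points": "" if s == "vasrrp" else s,
                        "statistic": stat,
                        "mean": vals.mean(),
                        "se": vals.std(ddof=1) if reps > 1 else np.nan,
                        "df": fits[0].df,
                        "reps": reps,
                    }
                )
        tables["table2_fit"] = AggregateTable(pd.DataFrame(rows), reps, dropped)

        # Table 3 analog: composite reliability from fitted parameters
        rows = []
        for s in scales:
            arr = np.array([rep["composite"][s] for rep in results])
            for l in range(L):
                rows.append(
                    {
                        "model": spec_ctcu.name,
                        "scale": scale_kind(s),
                        "cut_points": "" if s == "vasrrp" else s,
                        "latent": l + 1,
                        "statistic": "composite_reliability",
                        "mean": arr[:, l].mean(),
                        "se": arr[:, l].std(ddof=1) if reps > 1 else np.nan,
                        "reps": reps,
                    }
                )
        tables["table3_composite"] = AggregateTable(pd.DataFrame(rows), reps, dropped)

        # Table 4 analog: parameter recovery
        frames = []
        for s in scales:
            fits = [rep["fits"][s] for rep in results]
            summary = parameter_recovery_summary(fits, spec_ctcu)
            summary.insert(0, "cut_points", "" if s == "vasrrp" else s)
            summary.insert(0, "scale", scale_kind(s))
            summary.insert(0, "model", spec_ctcu.name)
            frames.append(summary)
        tables["table4_recovery"] = AggregateTable(
            pd.concat(frames, ignore_index=True), reps, dropped
        )

    clip = [rep["clip"] for rep in results if rep["clip"] is not None]
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "replications_completed": reps,
        "replications_dropped": dropped,
        "mean_clip_fraction": float(np.mean(clip)) if clip else None,
        "se_convention": (
            "SE columns report the SD of the replication distribution"
        ),
    }
    log_lines = [
        f"model={spec_ctcu.name} n={config.n} reps={reps} seed={config.seed}",
        f"dropped replications: {dropped}",
    ]
    if clip:
        log_lines.append(f"mean clip fraction: {np.mean(clip):.5f}")
    return SimulationResults(tables=tables, manifest=manifest, log_lines=log_lines)


def run_ranking_comparison(config: SimulationConfig) -> SimulationResults:
    """Study 2: factor one recorded-seed dataset as VAS-RRP scores and as
    within-testlet ranks, by principal components with promax rotation."""
    spec = config.resolve_spec()
    seed = config.seed + SIM2_STREAM_OFFSET
    data = generate_dataset(spec, config.n, seed)
    vas = to_vasrrp(data)
    ranks = to_ranking(vas)
    L = spec.n_latents

    struct_frames, corr_frames, summary_rows = [], [], []
    for name, values in (("VAS-RRP", vas.values), ("Ranking", ranks.values.astype(float))):
        C = np.corrcoef(values, rowvar=False)
        fit = rotate_oblique(extract_components(C, k=L))
        labels = [f"T{t + 1}_L{l + 1}" for t, l in zip(spec.item_to_testlet, spec.item_to_latent)]
        st = structure_table(fit.pattern, threshold=0.3, item_labels=labels)
        st.insert(0, "scale", name)
        st.insert(1, "item", labels)
        struct_frames.append(st.reset_index(drop=True))
        cc = pd.DataFrame(
            fit.component_corr,
            columns=[f"component_{j + 1}" for j in range(L)],
        )
        cc.insert(0, "scale", name)
        corr_frames.append(cc)
        alphas = [
            cronbach_alpha(values[:, spec.items_of_latent(l)]) for l in range(L)
        ]
        row = {"scale": name}
        row.update({f"alpha_{l + 1}": alphas[l] for l in range(L)})
        row["pve"] = fit.pve
        # simple structure: every item's largest |pattern| loading on its
        # generating latent's component
        assign = align_columns(fit.pattern, spec.item_to_latent)
        viol = sum(
            int(np.abs(fit.pattern[i]).argmax() != assign[spec.item_to_latent[i]])
            for i in range(spec.n_items)
        )
        row["complex_items"] = viol
        summary_rows.append(row)

    tables = {
        "sim2_structure": AggregateTable(
            pd.concat(struct_frames, ignore_index=True), 1
        ),
        "sim2_corr": AggregateTable(pd.concat(corr_frames, ignore_index=True), 1),
        "sim2_pve": AggregateTable(pd.DataFrame(summary_rows), 1),
    }
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "sim2_seed": seed,
    }
    return SimulationResults(
        tables=tables,
        manifest=manifest,
        log_lines=[f"study 2 dataset seed: {seed}"],
    )


def write_outputs(results: SimulationResults, outdir) -> list:
    """Write every aggregate table as CSV plus manifest.json and run.log;
    returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, agg in results.tables.items():
        path = outdir / f"{name}.csv"
        agg.table.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(results.manifest, indent=1, sort_keys=True))
    written.append(manifest_path)
    log_path = outdir / "run.log"
    log_path.write_text("\n".join(results.log_lines) + "\n")
    written.append(log_path)
    return written


def _merge_results(a: SimulationResults, b: SimulationResults) -> SimulationResults:
    tables = dict(a.tables)
    tables.update(b.tables)
    manifest = dict(a.manifest)
    manifest.update({k: v for k, v in b.manifest.items() if k not in manifest})
    return SimulationResults(
        tables=tables,
        manifest=manifest,
        log_lines=a.log_lines + b.log_lines,
    )


@click.command(name="vasrrp")
@click.argument("config_path", type=click.Path(exists=True, dir_okay=False))
@click.option("--reps", type=int, default=None, help="Override replication count.")
@click.option("--n", "n_override", type=int, default=None, help="Override sample size.")
@click.option("--seed", type=int, default=None, help="Override master seed.")
@click.option("--out", type=click.Path(file_okay=False), default=None, help="Override output directory.")
def cli_main(config_path, reps, n_override, seed, out):
    """Run the response-format simulation described by CONFIG_PATH (YAML)
    and write the aggregate tables, manifest and log to the output
    directory."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    try:
        config = SimulationConfig.from_yaml(config_path)
    except (ValueError, TypeError, yaml.YAMLError) as exc:
        click.echo(f"invalid config: {exc}", err=True)
        sys.exit(1)
    overrides = {}
    if reps is not None:
        overrides["replications"] = reps
    if n_override is not None:
        overrides["n"] = n_override
    if seed is not None:
        overrides["seed"] = seed
    if out is not None:
        overrides["outdir"] = out
    if overrides:
        config = replace(config, **overrides)
    try:
        results = run_simulation(config)
        if config.sim2:
            results = _merge_results(results, run_ranking_comparison(config))
    except RuntimeError as exc:
        click.echo(f"simulation failed: {exc}", err=True)
        # retain whatever was produced so far? tables exist only on success
        sys.exit(1)
    results.manifest["cli_overrides"] = overrides
    written = write_outputs(results, config.outdir)
    for path in written:
        logger.info("wrote %s", path)
    click.echo(f"wrote {len(written)} artifacts to {config.outdir}")
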