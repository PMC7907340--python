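"""End-to-end orchestration: simulate/load -> classify -> fit -> compare ->
bootstrap -> abundance -> RIP.

A :class:`RunConfig` (YAML or JSON) names either input tables or
simulation blocks for each data source, the analysis options, and an
output directory.  :func:`run_pipeline` executes the stages in order and
writes machine-readable result tables (fit parameters with SE/z/p,
pairwise differences, abundance summaries, RIP with CIs and exceedance
probability, curve data with bootstrap bands, biplot data) plus a
structured JSON log recording seeds, exclusions and convergence failures.

All randomness flows from one root seed, split per stage with
``numpy.random.SeedSequence`` so every stage is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .abundance import compare_abundance, summarize_abundance
from .model import classify_fr_type, compare_fits, fit_rogers
from .rip import EffectSummary, rip_biplot_data, rip_score
from .simulate import SimulationConfig, generate_quadrat_survey, generate_trials

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one of ``trials_path`` / ``trial_simulations`` and one of
    ``quadrats_path`` / ``quadrat_simulations`` must be set.  ``seed`` is
    mandatory whenever any stage is stochastic (simulation, bootstrap,
    RIP draws).
    """

    output_dir: str
    seed: int | None = None
    alpha: float = 0.05
    n_boot: int = 2000
    n_boot_feeding_rate: int = 30
    n_draws: int = 100_000
    feeding_rate_convention: str = "per_day"
    rip_law: str = "lognormal"
    trials_path: str | None = None
    trial_simulations: list = field(default_factory=list)
    quadrats_path: str | None = None
    quadrat_simulations: list = field(default_factory=list)
    rip_comparisons: list = field(default_factory=list)
    include_quadratic: bool = False

    def __post_init__(self):
        if bool(self.trials_path) == bool(self.trial_simulations):
            raise ValueError(
                "exactly one of trials_path or trial_simulations must be given"
            )
        if self.quadrats_path and self.quadrat_simulations:
            raise ValueError(
                "give either quadrats_path or quadrat_simulations, not both"
            )
        stochastic = bool(
            self.trial_simulations or self.quadrat_simulations or self.n_boot or self.n_draws
        )
        if stochastic and self.seed is None:
            raise ValueError("seed is mandatory for stochastic stages")
        if self.feeding_rate_convention not in ("per_day", "per_experiment"):
            raise ValueError(
                "feeding_rate_convention must be 'per_day' or 'per_experiment'"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
        return cls(**doc)


def _stage(log, name):
    log["stages"].append(name)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the result bundle and writes files.

    The bundle maps table names to DataFrames (plus the ``log`` dict);
    every table is also written as CSV under ``config.output_dir``.
    Stage failures raise with the stage name prepended.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = dict(
        zip(
            ("simulate_trials", "simulate_quadrats", "bootstrap", "rip"),
            root.spawn(4),
        )
    )
    log = {"seed": config.seed, "stages": [], "exclusions": [], "warnings": [],
           "bootstrap_failures": {}}
    bundle = {}

    def run_stage(name, fn):
        _stage(log, name)
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError("stage %r failed: %s" % (name, exc)) from exc

    # -- trials ---------------------------------------------------------
    def load_trials():
        if config.trials_path:
            return fio.read_trials(config.trials_path)
        rng = np.random.default_rng(seeds["simulate_trials"])
        frames = [
            generate_trials(SimulationConfig(**block), rng=rng)
            for block in config.trial_simulations
        ]
        return pd.concat(frames, ignore_index=True)

    trials = run_stage("trials", load_trials)
    excluded = trials[trials["excluded"].astype(bool)]
    log["exclusions"] = excluded["replicate_id"].tolist()
    bundle["trials"] = trials

    groups = [
        (name, sub)
        for name, sub in trials.groupby("predator_group", sort=False)
        if name != "control"
    ]

    # -- classification -------------------------------------------------
    def classify():
        rows = []
        for name, sub in groups:
            r = classify_fr_type(sub, include_quadratic=config.include_quadratic,
                                 alpha=config.alpha)
            rows.append(
                dict(
                    predator_group=name,
                    first_order_coef=r.first_order_coef,
                    first_order_se=r.first_order_se,
                    first_order_p=r.first_order_p,
                    second_order_coef=r.second_order_coef,
                    second_order_p=r.second_order_p,
                    dispersion=r.dispersion,
                    classified_type=r.classified_type,
                )
            )
        return pd.DataFrame(rows)

    bundle["fr_types"] = run_stage("classify", classify)

    # -- fits (Type II mechanistic model) --------------------------------
    fits = {}

    def fit_all():
        rows = []
        for name, sub in groups:
            res = fit_rogers(sub)
            fits[name] = res
            rows.append(
                dict(
                    predator_group=name,
                    n_trials=res.nobs,
                    duration_days=res.duration,
                    a=res.a,
                    se_a=res.bse["a"],
                    z_a=res.zvalues["a"],
                    p_a=res.pvalues["a"],
                    h=res.h,
                    se_h=res.bse["h"],
                    z_h=res.zvalues["h"],
                    p_h=res.pvalues["h"],
                    log_likelihood=res.llf,
                    converged=res.converged,
                    max_feeding_rate=res.max_feeding_rate,
                    max_feeding_rate_per_day=res.max_feeding_rate_per_day,
                )
            )
        return pd.DataFrame(rows)

    bundle["fits"] = run_stage("fit", fit_all)

    # -- pairwise comparisons -------------------------------------------
    def compare_all():
        rows = []
        names = list(fits)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                base, comp = names[i], names[j]
                cmp_ = compare_fits(
                    trials[trials["predator_group"] == base],
                    trials[trials["predator_group"] == comp],
                )
                rows.append(
                    dict(
                        base_group=base,
                        comparator_group=comp,
                        Da=cmp_.Da, se_Da=cmp_.se_Da, z_Da=cmp_.z_Da, p_Da=cmp_.p_Da,
                        Dh=cmp_.Dh, se_Dh=cmp_.se_Dh, z_Dh=cmp_.z_Dh, p_Dh=cmp_.p_Dh,
                    )
                )
        return pd.DataFrame(rows)

    bundle["comparisons"] = run_stage("compare", compare_all)

    # -- bootstrap -------------------------------------------------------
    ensembles = {}

    def bootstrap_all():
        boot_seeds = seeds["bootstrap"].spawn(2 * len(fits))
        bands = {}
        fr_rows = []
        for k, (name, res) in enumerate(fits.items()):
            bands_ens = res.bootstrap(n_boot=config.n_boot, seed=boot_seeds[2 * k])
            fr_ens = res.bootstrap(
                n_boot=config.n_boot_feeding_rate, seed=boot_seeds[2 * k + 1]
            )
            ensembles[name] = fr_ens
            log["bootstrap_failures"][name] = dict(
                bands=bands_ens.n_failed, feeding_rate=fr_ens.n_failed
            )
            bands[name] = bands_ens.band_frame().assign(predator_group=name)
            fr_rows.append(
                dict(
                    predator_group=name,
                    n_boot=fr_ens.n_boot,
                    max_feeding_rate_mean=fr_ens.max_feeding_rate_mean,
                    max_feeding_rate_se=fr_ens.max_feeding_rate_se,
                    max_feeding_rate_per_day_mean=fr_ens.max_feeding_rate_per_day_mean,
                    max_feeding_rate_per_day_se=fr_ens.max_feeding_rate_per_day_se,
                )
            )
        return pd.concat(bands.values(), ignore_index=True), pd.DataFrame(fr_rows)

    bundle["fr_bands"], bundle["feeding_rates"] = run_stage("bootstrap", bootstrap_all)

    # -- abundance -------------------------------------------------------
    quadrats = None
    if config.quadrats_path or config.quadrat_simulations:

        def load_quadrats():
            if config.quadrats_path:
                return fio.read_quadrats(config.quadrats_path)
            rng = np.random.default_rng(seeds["simulate_quadrats"])
            frames = [
                generate_quadrat_survey(rng=rng, **block)
                for block in config.quadrat_simulations
            ]
            return pd.concat(frames, ignore_index=True)

        quadrats = run_stage("quadrats", load_quadrats)
        bundle["quadrats"] = quadrats

        def summarize():
            summaries = summarize_abundance(quadrats)
            return pd.DataFrame([dataclasses.asdict(s) for s in summaries])

        bundle["abundance"] = run_stage("abundance", summarize)

        def compare_ab():
            cmp_ = compare_abundance(quadrats)
            omni = pd.DataFrame(
                [dict(f_statistic=cmp_.f_statistic, df_num=cmp_.df_num,
                      df_den=cmp_.df_den, pvalue=cmp_.pvalue,
                      dispersion=cmp_.dispersion)]
            )
            return omni, cmp_.pairwise

        bundle["abundance_omnibus"], bundle["abundance_pairwise"] = run_stage(
            "abundance_compare", compare_ab
        )

    # -- RIP -------------------------------------------------------------
    if quadrats is not None and config.rip_comparisons:

        def build_effects():
            ab = {row["group"]: row for _, row in bundle["abundance"].iterrows()}
            effects = {}
            per_day = config.feeding_rate_convention == "per_day"
            for name, ens in ensembles.items():
                if name not in ab:
                    continue
                effects[name] = EffectSummary(
                    label=name,
                    fr_mean=(ens.max_feeding_rate_per_day_mean if per_day
                             else ens.max_feeding_rate_mean),
                    fr_se=(ens.max_feeding_rate_per_day_se if per_day
                           else ens.max_feeding_rate_se),
                    abundance_mean=ab[name]["mean_density"],
                    abundance_se=ab[name]["se_density"],
                )
            return effects

        effects = run_stage("effects", build_effects)

        def rip_all():
            rip_seeds = seeds["rip"].spawn(len(config.rip_comparisons))
            rows = []
            for s, (base, comp) in zip(rip_seeds, config.rip_comparisons):
                r = rip_score(
                    effects[base], effects[comp], n_draws=config.n_draws,
                    seed=s, law=config.rip_law, keep_draws=False,
                )
                rows.append(
                    dict(
                        base_group=base,
                        comparator_group=comp,
                        rip_mean=r.rip_mean,
                        ci80_low=r.ci80[0], ci80_high=r.ci80[1],
                        ci60_low=r.ci60[0], ci60_high=r.ci60[1],
                        prob_rip_exceeds_1_pct=r.prob_exceeds_one,
                        n_draws=r.n_draws,
                    )
                )
            return pd.DataFrame(rows)

        bundle["rip"] = run_stage("rip", rip_all)

        def biplot():
            data = rip_biplot_data(list(effects.values()))
            pts = pd.DataFrame(data["points"])
            iso = pd.concat(
                [
                    pd.DataFrame(dict(label=i["label"], x=i["x"], y=i["y"]))
                    for i in data["isoclines"]
                ],
                ignore_index=True,
            )
            return pts, iso

        bundle["biplot_points"], bundle["biplot_isoclines"] = run_stage("biplot", biplot)

    # -- write -----------------------------------------------------------
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    bundle["log"] = log
    return bundle
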