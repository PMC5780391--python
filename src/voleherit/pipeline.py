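"""Workflow orchestration: simulate -> fit -> report, recovery experiments,
and the behaviour/correlation screen.

Workflows are pure functions of (config, inputs): they never mutate their
inputs, derive all randomness from the config seed, and stamp every report
with the seed and a hash of the configuration so a run can be reproduced
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .behaviour import paired_before_after, partner_preference_summary, spearman_screen
from .model import AnimalModel, GibbsConfig, PriorSpec
from .pedigree import Pedigree, additive_relationship_matrix, validate_and_sort

__all__ = [
    "RunConfig",
    "run_simulation",
    "run_heritability",
    "run_recovery_experiment",
    "run_behaviour_screen",
]

logger = logging.getLogger("voleherit")

CHAIN_PRESETS = {"production": GibbsConfig.production, "fast": GibbsConfig.fast}


@dataclass
class RunConfig:
    """Configuration for the pipeline workflows (YAML-loadable).

    All analysis thresholds live here: the chain schedule, prior
    hyperparameters, Bonferroni family sizes and the recovery-experiment
    grid.  The shipped defaults are the production analysis settings.
    """

    seed: int = 0
    # chain schedule
    chain_preset: str = "production"
    n_iter: Optional[int] = None
    burn_in: Optional[int] = None
    thin: Optional[int] = None
    # priors (uniform across components by default)
    prior_nu0: float = 0.002
    prior_S0: float = 1.0
    # model structure
    effects: tuple[str, ...] = ("male", "partner", "stranger")
    traits: tuple[str, ...] = ()
    standardize: bool = False
    # multiple-testing families
    paired_family_size: int = 13
    screen_family_size: Optional[int] = None
    base_alpha: float = 0.05
    # synthetic colony
    n_founder_blocks: int = 13
    n_generations: int = 2
    litter_size: int = 5
    # recovery experiment
    recovery_h2_grid: tuple[float, ...] = (0.0, 0.5, 0.8)
    recovery_replicates: int = 3
    recovery_total_variance: float = 4.0
    recovery_beta: float = 59.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("effects", "traits", "recovery_h2_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def gibbs_config(self, seed: Optional[int] = None) -> GibbsConfig:
        seed = self.seed if seed is None else seed
        if self.n_iter is not None:
            return GibbsConfig(
                self.n_iter, self.burn_in or 0, self.thin or 1, seed
            )
        return CHAIN_PRESETS[self.chain_preset](seed)

    def priors(self) -> PriorSpec:
        nu0, S0 = self.prior_nu0, self.prior_S0
        return PriorSpec(
            nu0_m=nu0, S0_m=S0, nu0_p=nu0, S0_p=S0,
            nu0_s=nu0, S0_s=S0, nu0_e=nu0, S0_e=S0,
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed}


def _derived_seed(base: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and an index key."""
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_simulation(config: RunConfig, out_dir: Optional[Path] = None):
    """Build a synthetic colony and phenotypes; optionally write the three
    artefacts (pedigree CSV, trials CSV, truth JSON)."""
    t0 = time.perf_counter()
    pedigree = simulate.generate_colony_pedigree(
        config.n_founder_blocks, config.n_generations, config.litter_size,
        seed=config.seed,
    )
    A = additive_relationship_matrix(pedigree)
    triples = simulate.assign_partners_strangers(
        pedigree, seed=_derived_seed(config.seed, 1), A=A
    )
    truth = simulate.VarianceTruth.from_heritability(
        0.5, beta=config.recovery_beta, total=config.recovery_total_variance
    )
    dataset = simulate.simulate_phenotypes(
        pedigree, triples, truth, seed=_derived_seed(config.seed, 2), A=A
    )
    logger.info(
        "simulated colony: %d animals, %d trials (%.2fs)",
        len(pedigree), len(dataset.trials), time.perf_counter() - t0,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .pedigree import write_pedigree

        write_pedigree(pedigree, out_dir / "pedigree.csv")
        dataset.write(out_dir / "trials.csv", out_dir / "truth.json")
    return pedigree, dataset


def run_heritability(
    config: RunConfig, trials: pd.DataFrame, pedigree: Pedigree
) -> dict:
    """Fit the animal model for each configured trait and report estimates.

    Returns a JSON-able report: per trait the posterior means/SDs of the
    variance components, the heritability posteriors and convergence
    diagnostics, plus provenance (seed, config hash, chain schedule).
    """
    pedigree = validate_and_sort(pedigree)
    A = additive_relationship_matrix(pedigree)
    traits = config.traits or tuple(sorted(trials["trait"].unique()))
    report: dict = {**config.provenance(), "traits": {}}
    for t_idx, trait in enumerate(traits):
        if trait not in set(trials["trait"]):
            raise ValueError(f"trait {trait!r} absent from trials table")
        t0 = time.perf_counter()
        model = AnimalModel.from_trials(
            trials, A, trait=trait, effects=config.effects,
            priors=config.priors(), standardize=config.standardize,
        )
        cfg = config.gibbs_config(seed=_derived_seed(config.seed, 10, t_idx))
        results = model.fit(cfg)
        h2 = results.heritability()
        diag = results.diagnostics()
        report["traits"][trait] = {
            "chain": {
                "n_iter": cfg.n_iter, "burn_in": cfg.burn_in,
                "thin": cfg.thin, "retained": cfg.n_retained, "seed": cfg.seed,
            },
            "posterior_mean": results.posterior_mean().to_dict(),
            "posterior_sd": results.posterior_sd().to_dict(),
            "heritability": h2.as_dict(),
            "ess": diag["ess"].to_dict(),
            "wall_seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info(
            "fitted trait %r: %d retained draws in %.1fs",
            trait, cfg.n_retained, report["traits"][trait]["wall_seconds"],
        )
    return report


def run_recovery_experiment(config: RunConfig) -> pd.DataFrame:
    """Parameter-recovery experiment over a grid of true heritabilities.

    For each truth x replicate: simulate a colony under the crossing
    scheme, generate phenotypes with the given true h2 for the focal-male
    effect (partner/stranger at zero), fit the full three-effect model,
    and score the posterior-mean heritabilities against truth.
    Deterministic given the config seed.
    """
    if config.recovery_replicates < 1:
        raise ValueError("recovery_replicates must be >= 1")
    pedigree = simulate.generate_colony_pedigree(
        config.n_founder_blocks, config.n_generations, config.litter_size,
        seed=config.seed,
    )
    if not simulate.experimental_males(pedigree):
        raise ValueError("design yields no phenotyped males")
    A = additive_relationship_matrix(pedigree)
    rows = []
    for i, h2_true in enumerate(config.recovery_h2_grid):
        truth = simulate.VarianceTruth.from_heritability(
            h2_true, beta=config.recovery_beta,
            total=config.recovery_total_variance,
        )
        for rep in range(config.recovery_replicates):
            triples = simulate.assign_partners_strangers(
                pedigree, seed=_derived_seed(config.seed, 3, i, rep), A=A
            )
            dataset = simulate.simulate_phenotypes(
                pedigree, triples, truth,
                seed=_derived_seed(config.seed, 4, i, rep), A=A,
            )
            model = AnimalModel.from_trials(
                dataset.trials, A, effects=config.effects, priors=config.priors()
            )
            cfg = config.gibbs_config(seed=_derived_seed(config.seed, 5, i, rep))
            h2 = model.fit(cfg).heritability()
            rows.append(
                {
                    "truth_h2_m": h2_true,
                    "replicate": rep,
                    "n_trials": len(dataset.trials),
                    "post_mean_h2_m": h2.mean.get("h2_male", np.nan),
                    "post_sd_h2_m": h2.sd.get("h2_male", np.nan),
                    "post_mean_h2_p": h2.mean.get("h2_partner", np.nan),
                    "post_mean_h2_s": h2.mean.get("h2_stranger", np.nan),
                    "abs_error_h2_m": abs(
                        h2.mean.get("h2_male", np.nan) - h2_true
                    ),
                }
            )
            logger.info(
                "recovery truth=%.2f rep=%d: posterior mean h2_m=%.3f",
                h2_true, rep, rows[-1]["post_mean_h2_m"],
            )
    frame = pd.DataFrame(rows)
    frame.attrs.update(config.provenance())
    return frame


def run_behaviour_screen(
    config: RunConfig,
    behaviours: pd.DataFrame,
    densities: Optional[pd.DataFrame] = None,
) -> dict:
    """Paired-comparison table, partner-preference summary and (when density
    data are supplied and non-empty) the Spearman screen."""
    report: dict = {**config.provenance()}
    paired_input = behaviours[behaviours["assay"] != "partner_preference"]
    report["paired"] = paired_before_after(
        paired_input, base_alpha=config.base_alpha,
        family_size=config.paired_family_size,
    )
    pp = behaviours[
        (behaviours["assay"] == "partner_preference")
        & (behaviours["behaviour"] == "partner_contact")
    ]
    if not pp.empty:
        report["partner_preference"] = partner_preference_summary(
            pp["value"].to_numpy()
        )
    if densities is not None and not densities.empty:
        report["spearman"] = spearman_screen(
            behaviours[behaviours["assay"] != "partner_preference"],
            densities,
            base_alpha=config.base_alpha,
            family_size=config.screen_family_size,
        )
    else:
        logger.warning("no density data supplied; Spearman screen omitted")
    return report
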