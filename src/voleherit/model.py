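"""Bayesian animal model with direct and indirect (social) genetic effects.

The observation model for one trial on focal male *i* tested with
partner *j* and stranger *k* is

    y = 1 beta + Z_m m + Z_p p + Z_s s + e,

where ``m``, ``p`` and ``s`` are additive genetic effect vectors over
the whole pedigree, each distributed N(0, A sigma2) with ``A`` the
numerator relationship matrix, and residuals are i.i.d. N(0, sigma2_e).
The partner and stranger terms are indirect genetic effects: the
contribution of a social partner's genotype to the focal animal's
phenotype.  Narrow-sense heritability of each effect is its variance
divided by the total sigma2_m + sigma2_p + sigma2_s + sigma2_e.

Estimation is by Gibbs sampling with conjugate full conditionals:

* the intercept from its normal conditional (flat prior);
* each effect vector as one multivariate-normal block draw with
  precision ``Z'Z / sigma2_e + A^{-1} / sigma2_x``;
* each variance from a scaled-inverse-chi-square with degrees
  ``q + nu0`` and scale ``(u' A^{-1} u + nu0 S0) / (q + nu0)`` (the
  residual variance analogously from the residual sum of squares).

Because ``Z'Z`` is diagonal (each trial hits one animal per effect) and
fixed, the pair ``(Z'Z, A^{-1})`` is simultaneously diagonalised once by
a generalised eigendecomposition; every subsequent block draw then costs
two matrix-vector products, which keeps full-length chains cheap even
with three effect vectors over several hundred animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .diagnostics import convergence_diagnostics
from .pedigree import Pedigree, RelationshipMatrix, inverse_relationship

__all__ = [
    "PriorSpec",
    "GibbsConfig",
    "PosteriorSamples",
    "HeritabilityEstimate",
    "AnimalModel",
    "AnimalModelResults",
    "SamplerError",
    "gibbs_fit",
    "heritability_from_samples",
    "parent_offspring_regression",
    "ParentOffspringRegression",
]

EFFECTS = ("male", "partner", "stranger")


class SamplerError(RuntimeError):
    """Raised when a chain diverges (non-finite or overflowing draws)."""


@dataclass(frozen=True)
class PriorSpec:
    """Scaled-inverse-chi-square priors for the variance components.

    ``nu0`` is the prior degrees of belief and ``S0`` the prior scale for
    each component; the defaults (nu0 = 0.002, S0 = 1) are near-
    noninformative while remaining proper.  The intercept prior is flat.
    """

    nu0_m: float = 0.002
    S0_m: float = 1.0
    nu0_p: float = 0.002
    S0_p: float = 1.0
    nu0_s: float = 0.002
    S0_s: float = 1.0
    nu0_e: float = 0.002
    S0_e: float = 1.0

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value <= 0:
                raise ValueError(f"prior hyperparameter {name} must be > 0")

    def nu0(self, component: str) -> float:
        return getattr(self, f"nu0_{component[0]}" if component != "e" else "nu0_e")

    def S0(self, component: str) -> float:
        return getattr(self, f"S0_{component[0]}" if component != "e" else "S0_e")


@dataclass(frozen=True)
class GibbsConfig:
    """Chain schedule: total iterations, burn-in discarded, thinning interval."""

    n_iter: int = 280_000
    burn_in: int = 30_000
    thin: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.thin <= 0:
            raise ValueError("n_iter and thin must be positive")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if (self.n_iter - self.burn_in) % self.thin:
            raise ValueError("(n_iter - burn_in) must be divisible by thin")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def production(cls, seed: int = 0) -> "GibbsConfig":
        """Production schedule: 280,000 iterations, 30,000 burn-in, thin 25
        (10,000 retained draws)."""
        return cls(280_000, 30_000, 25, seed)

    @classmethod
    def fast(cls, seed: int = 0) -> "GibbsConfig":
        """Desk-speed schedule (28,000 / 3,000 / 25; 1,000 retained draws)."""
        return cls(28_000, 3_000, 25, seed)


@dataclass(frozen=True)
class PosteriorSamples:
    """Retained Gibbs draws, one row per stored iteration."""

    frame: pd.DataFrame = field(repr=False)  # beta, var_<effect>..., var_e
    config: GibbsConfig
    effects: tuple[str, ...]

    @property
    def n_draws(self) -> int:
        return len(self.frame)

    def variance_columns(self) -> list[str]:
        return [f"var_{x}" for x in self.effects] + ["var_e"]

    def total_variance(self) -> np.ndarray:
        return self.frame[self.variance_columns()].to_numpy().sum(axis=1)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Posterior mean and SD of each variance ratio h2_x = var_x / var_total."""

    mean: dict[str, float]
    sd: dict[str, float]
    per_draw: pd.DataFrame = field(repr=False)

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            x: {"mean": self.mean[x], "sd": self.sd[x]} for x in self.mean
        }


def heritability_from_samples(samples: PosteriorSamples) -> HeritabilityEstimate:
    """Per-draw variance ratios, then their posterior mean and SD.

    The ratio is computed for every retained draw and averaged (the
    mean-of-ratios posterior functional); the SD across draws is the
    reported standard error.
    """
    if samples.n_draws == 0:
        raise ValueError("no retained draws")
    total = samples.total_variance()
    if np.any(total <= 0):
        raise ValueError("degenerate draw with non-positive total variance")
    ratios = {
        f"h2_{x}": samples.frame[f"var_{x}"].to_numpy() / total
        for x in samples.effects
    }
    per_draw = pd.DataFrame(ratios)
    return HeritabilityEstimate(
        mean={k: float(v.mean()) for k, v in per_draw.items()},
        sd={k: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for k, v in per_draw.items()},
        per_draw=per_draw,
    )


class AnimalModel:
    """Mixed model y = 1 beta + Z_m m + Z_p p + Z_s s + e over a pedigree.

    Parameters
    ----------
    endog : array-like
        Trait values, one per trial (seconds for behaviours, optical
        density units for receptor traits).
    trial_animals : mapping
        For each active effect ("male", "partner", "stranger"), the animal
        id carrying that effect in each trial.  Omit an entry (or pass
        ``effects``) to drop the corresponding genetic term — e.g. density
        traits measured without social context use a male-effect-only model.
    relationship : RelationshipMatrix
        Numerator relationship matrix over (at least) all referenced animals.
    priors : PriorSpec, optional
    standardize : bool
        If true, fit on z-scored trait values (ratios are scale-free, so
        heritabilities are unchanged; variance draws are in SD^2 units).
    """

    def __init__(
        self,
        endog,
        trial_animals: dict[str, Sequence[str]],
        relationship: RelationshipMatrix,
        priors: Optional[PriorSpec] = None,
        standardize: bool = False,
    ):
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.ndim != 1 or self.endog.size == 0:
            raise ValueError("endog must be a non-empty 1-d array")
        self.effects = tuple(x for x in EFFECTS if x in trial_animals)
        self.relationship = relationship
        self.priors = priors or PriorSpec()
        self.standardize = standardize
        self._scale = self.endog.std(ddof=1) if standardize else 1.0
        if standardize:
            if self._scale == 0:
                raise ValueError("cannot standardize a constant trait")
            self.endog = (self.endog - self.endog.mean()) / self._scale
        self._indices: dict[str, np.ndarray] = {}
        for x in self.effects:
            ids = list(trial_animals[x])
            if len(ids) != self.endog.size:
                raise ValueError(f"{x} ids and endog differ in length")
            try:
                self._indices[x] = np.array(
                    [relationship.index_of(a) for a in ids], dtype=np.intp
                )
            except KeyError as exc:
                raise ValueError(f"animal {exc.args[0]!r} not in relationship matrix")

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_trials(
        cls,
        trials: pd.DataFrame,
        relationship: RelationshipMatrix,
        trait: Optional[str] = None,
        effects: Sequence[str] = EFFECTS,
        priors: Optional[PriorSpec] = None,
        standardize: bool = False,
    ) -> "AnimalModel":
        """Build from a long trials table (columns male, partner, stranger,
        trait, value), optionally restricted to one trait label."""
        if trait is not None:
            trials = trials[trials["trait"] == trait]
            if trials.empty:
                raise ValueError(f"trait {trait!r} not present in trials table")
        unknown = set(effects) - set(EFFECTS)
        if unknown:
            raise ValueError(f"unknown effects {sorted(unknown)}")
        trial_animals = {
            x: trials[x].tolist() for x in effects if x in trials.columns
        }
        return cls(
            trials["value"].to_numpy(dtype=float),
            trial_animals,
            relationship,
            priors=priors,
            standardize=standardize,
        )

    # -- estimation ----------------------------------------------------------
    def fit(self, config: Optional[GibbsConfig] = None) -> "AnimalModelResults":
        """Run the Gibbs sampler and return results with retained draws."""
        config = config or GibbsConfig.fast()
        samples = self._run_gibbs(config)
        return AnimalModelResults(self, samples)

    def _run_gibbs(self, config: GibbsConfig) -> PosteriorSamples:
        rng = np.random.default_rng(config.seed)
        y = self.endog
        n = y.size
        q = len(self.relationship)
        priors = self.priors

        # one-off setup: simultaneous diagonalisation of (Z'Z, A^-1) per effect
        if self.effects:
            Ainv = inverse_relationship(self.relationship)
        basis: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        counts: dict[str, np.ndarray] = {}
        for x in self.effects:
            c = np.bincount(self._indices[x], minlength=q).astype(float)
            lam, Q = scipy.linalg.eigh(np.diag(c), Ainv)
            basis[x] = (np.clip(lam, 0.0, None), np.ascontiguousarray(Q))
            counts[x] = c

        # initial state
        beta = float(y.mean())
        var_y = float(y.var(ddof=1)) or 1.0
        variances = {x: var_y / (len(self.effects) + 1) for x in self.effects}
        var_e = var_y / (len(self.effects) + 1)
        u = {x: np.zeros(q) for x in self.effects}
        contrib = {x: np.zeros(n) for x in self.effects}

        kept = np.empty((config.n_retained, 2 + len(self.effects)))
        row = 0
        for it in range(1, config.n_iter + 1):
            # intercept | rest  (flat prior)
            resid0 = y.copy()
            for x in self.effects:
                resid0 -= contrib[x]
            beta = rng.normal(resid0.mean(), np.sqrt(var_e / n))

            # effect blocks | rest
            for x in self.effects:
                r = y - beta
                for other in self.effects:
                    if other != x:
                        r -= contrib[other]
                lam, Q = basis[x]
                d = 1.0 / variances[x] + lam / var_e
                rhs = np.bincount(self._indices[x], weights=r, minlength=q) / var_e
                w = (Q.T @ rhs) / d + rng.standard_normal(q) / np.sqrt(d)
                u[x] = Q @ w
                contrib[x] = u[x][self._indices[x]]
                # u' A^-1 u in the diagonalised basis is just w'w
                quad = float(w @ w)
                nu0, S0 = priors.nu0(x), priors.S0(x)
                variances[x] = (quad + nu0 * S0) / rng.chisquare(q + nu0)

            # residual variance | rest
            resid = y - beta
            for x in self.effects:
                resid -= contrib[x]
            sse = float(resid @ resid)
            var_e = (sse + priors.nu0_e * priors.S0_e) / rng.chisquare(n + priors.nu0_e)

            if not np.isfinite(var_e) or var_e > 1e300:
                raise SamplerError(f"residual variance diverged at iteration {it}")

            if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
                kept[row, 0] = beta
                for j, x in enumerate(self.effects):
                    kept[row, 1 + j] = variances[x]
                kept[row, -1] = var_e
                row += 1

        columns = ["beta"] + [f"var_{x}" for x in self.effects] + ["var_e"]
        frame = pd.DataFrame(kept, columns=columns)
        if not np.isfinite(frame.to_numpy()).all():
            raise SamplerError("non-finite draws retained")
        return PosteriorSamples(frame=frame, config=config, effects=self.effects)


class AnimalModelResults:
    """Fit results: retained draws, heritability posteriors, diagnostics."""

    def __init__(self, model: AnimalModel, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    @property
    def config(self) -> GibbsConfig:
        return self.samples.config

    def posterior_mean(self) -> pd.Series:
        return self.samples.frame.mean()

    def posterior_sd(self) -> pd.Series:
        return self.samples.frame.std(ddof=1)

    def heritability(self) -> HeritabilityEstimate:
        return heritability_from_samples(self.samples)

    def diagnostics(self, max_lag: int = 10) -> pd.DataFrame:
        return convergence_diagnostics(self.samples, max_lag=max_lag)

    def plot_trace(self, params: Optional[Sequence[str]] = None):
        """Trace plots of retained draws (one axis per parameter)."""
        import matplotlib.pyplot as plt

        params = list(params or self.samples.frame.columns)
        fig, axes = plt.subplots(len(params), 1, figsize=(8, 2 * len(params)),
                                 squeeze=False, sharex=True)
        for ax, name in zip(axes[:, 0], params):
            ax.plot(self.samples.frame[name].to_numpy(), lw=0.4)
            ax.set_ylabel(name)
        axes[-1, 0].set_xlabel("retained draw")
        fig.tight_layout()
        return fig

    def summary(self) -> str:
        """Readable report: posterior means/SDs, heritabilities, ESS."""
        mean, sd = self.posterior_mean(), self.posterior_sd()
        try:
            diag = self.diagnostics()
            ess = diag["ess"]
        except ValueError:
            ess = pd.Series(np.nan, index=self.samples.frame.columns)
        h2 = self.heritability() if self.samples.effects else None
        cfg = self.config
        lines = [
            "Animal model (Gibbs sampler)",
            "=" * 58,
            f"trials: {self.model.endog.size}   animals in A: {len(self.model.relationship)}",
            f"effects: {', '.join(self.samples.effects) or '(intercept + residual only)'}",
            f"chain: {cfg.n_iter} iterations, burn-in {cfg.burn_in}, thin {cfg.thin}"
            f" -> {cfg.n_retained} retained (seed {cfg.seed})",
            "-" * 58,
            f"{'parameter':<12}{'post. mean':>12}{'post. SD':>12}{'ESS':>10}",
        ]
        for name in self.samples.frame.columns:
            lines.append(
                f"{name:<12}{mean[name]:>12.4f}{sd[name]:>12.4f}{ess[name]:>10.0f}"
            )
        if h2 is not None:
            lines.append("-" * 58)
            for name in h2.mean:
                lines.append(
                    f"{name:<12}{h2.mean[name]:>12.4f}{h2.sd[name]:>12.4f}{'':>10}"
                )
        lines.append("=" * 58)
        return "\n".join(lines)


def gibbs_fit(
    trials: pd.DataFrame,
    relationship: RelationshipMatrix,
    priors: Optional[PriorSpec] = None,
    config: Optional[GibbsConfig] = None,
    trait: Optional[str] = None,
    effects: Sequence[str] = EFFECTS,
) -> PosteriorSamples:
    """Functional wrapper: build :class:`AnimalModel` from a trials table and
    return the retained posterior draws."""
    model = AnimalModel.from_trials(
        trials, relationship, trait=trait, effects=effects, priors=priors
    )
    return model.fit(config).samples


@dataclass(frozen=True)
class ParentOffspringRegression:
    """Single-parent regression heritability: h2 = 2 * slope of offspring on sire."""

    h2: float
    se: float
    slope: float
    slope_se: float
    n_pairs: int

    @property
    def out_of_range(self) -> bool:
        """True when the estimate falls outside the parameter space [0, 1]."""
        return not 0.0 <= self.h2 <= 1.0


def parent_offspring_regression(
    trials: pd.DataFrame, pedigree: Pedigree, trait: Optional[str] = None
) -> ParentOffspringRegression:
    """Regress male offspring phenotype on sire phenotype; h2 is twice the slope.

    Accepts a trials table with a ``male`` (or ``animal``) column and
    ``value``; each sire-son pair with both phenotypes measured is one
    observation.  The reported standard error is twice the slope's SE.
    Out-of-range estimates are reported as-is and flagged.
    """
    from scipy import stats

    frame = trials if trait is None else trials[trials["trait"] == trait]
    col = "male" if "male" in frame.columns else "animal"
    values = frame.groupby(col)["value"].mean()
    pairs = []
    for animal in values.index:
        if animal not in pedigree:
            continue
        rec = pedigree[animal]
        if rec.sex not in (None, "M"):
            continue
        sire = rec.sire_id
        if sire is not None and sire in values.index:
            pairs.append((values[sire], values[animal]))
    if len(pairs) < 2:
        raise ValueError("need at least two sire-son phenotype pairs")
    x, y = np.array(pairs).T
    if np.all(x == x[0]):
        raise ValueError("no variation among sire phenotypes")
    fit = stats.linregress(x, y)
    return ParentOffspringRegression(
        h2=2.0 * fit.slope,
        se=2.0 * fit.stderr,
        slope=fit.slope,
        slope_se=fit.stderr,
        n_pairs=len(pairs),
    )
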