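"""Composite-likelihood fitting of demographic models to observed SFS.

The fit follows the standard two-step simulation-based approximate
likelihood scheme: the composite log10-likelihood of an observed SNP
spectrum under a model is ``sum_i obs_i * log10(max(exp_i, floor))`` over
polymorphic cells, where ``exp_i`` is the expected proportion from
simulation and ``floor = 1 / (10 * n_sims)`` guards cells unobserved among
the simulated genealogies.  Parameters are searched on the all-SNP spectrum
by cycles of conditional maximization (one parameter at a time on a log10
scale, against freshly simulated expected spectra with common random numbers
within a cycle), then each model is evaluated once at its estimates against
the one-SNP-per-locus spectrum with a much larger simulation count, giving
the AIC ``2k - 2 ln(10) * log10 CL`` used for ranking.  Uncertainty comes
from a parametric bootstrap: resimulate observed spectra at the best
estimates, refit each, and take percentile intervals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from haplodem.coalsim import SimulationConfig, sample_observed_sfs, simulate_expected_sfs
from haplodem.models import ModelBuilder
from haplodem.sfs import JointSFS

LN10 = math.log(10.0)


@dataclass
class FitResult:
    """Best parameters and composite likelihood for one model."""

    model_name: str
    estimates: dict[str, float]
    log10_cl: float
    max_log10_cl: float
    k: int
    aic: float | None = None
    run_meta: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "model_name": self.model_name,
            "estimates": self.estimates,
            "log10_cl": self.log10_cl,
            "max_log10_cl": self.max_log10_cl,
            "k": self.k,
            "aic": self.aic,
            "run_meta": self.run_meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FitResult":
        try:
            with open(source) as fh:
                data = json.load(fh)
        except (OSError, TypeError):
            data = json.loads(source)
        return cls(**data)


@dataclass
class BootstrapResult:
    """Parametric-bootstrap replicate estimates and percentile CIs."""

    replicates: pd.DataFrame  # one row per replicate, one column per parameter
    ci: pd.DataFrame          # index: parameter; columns: low, high
    n_requested: int
    n_dropped: int = 0


def composite_log10_likelihood(
    obs: JointSFS,
    exp: JointSFS,
    n_sims: int | None = None,
    expected_snps: float | None = None,
) -> float:
    """Multinomial composite log10-likelihood over polymorphic cells.

    ``exp`` must be an expected-proportion SFS; cells below the simulation
    floor ``1/(10 n_sims)`` (``n_sims`` from the argument or ``exp.meta``)
    are floored.  Monomorphic corner cells are excluded.  Observed masses may
    be fractional (projection output).

    A SNP-only proportion likelihood is invariant to a joint rescaling of
    all sizes and times; when ``expected_snps`` (the model's expected total
    polymorphic-site count, ``n_loci * mu * L * E[total branch length]``) is
    given, a Poisson term for the observed total is added, which identifies
    the absolute scale through the fixed mutation rate.
    """
    if exp.pop_labels != obs.pop_labels and set(exp.pop_labels) == set(
        obs.pop_labels
    ):
        exp = exp.transposed(obs.pop_labels)
    if obs.counts.shape != exp.counts.shape:
        raise ValueError(
            f"shape mismatch: obs {obs.counts.shape} ({obs.pop_labels}) vs "
            f"exp {exp.counts.shape} ({exp.pop_labels})"
        )
    if n_sims is None:
        n_sims = exp.meta.get("n_sims")
    floor = 1.0 / (10.0 * n_sims) if n_sims else 1e-300
    mask = obs.polymorphic_mask()
    o = obs.counts[mask]
    p = np.maximum(exp.counts[mask], floor)
    nz = o > 0
    cl = float(np.sum(o[nz] * np.log10(p[nz])))
    if expected_snps is not None:
        s = float(o.sum())
        lam = max(float(expected_snps), 1e-300)
        cl += s * math.log10(lam) - lam / LN10 - gammaln(s + 1.0) / LN10
    return cl


def saturated_log10_likelihood(obs: JointSFS, include_total: bool = False) -> float:
    """Composite log10-likelihood ceiling: obs evaluated at its own proportions.

    With ``include_total`` the Poisson total-count term is maximized at
    ``lambda = S`` and added, matching fits that use the scale term.
    """
    mask = obs.polymorphic_mask()
    o = obs.counts[mask]
    total = float(o.sum())
    if total <= 0:
        return 0.0
    nz = o > 0
    cl = float(np.sum(o[nz] * np.log10(o[nz] / total)))
    if include_total:
        cl += total * math.log10(total) - total / LN10 - gammaln(total + 1.0) / LN10
    return cl


def _eval_seed(seed: int, run: int, cycle: int) -> int:
    return (seed * 1_000_003 + run * 8_191 + cycle * 131 + 7) & 0x7FFFFFFF


def _objective(
    params: dict[str, float],
    builder: ModelBuilder,
    obs: JointSFS,
    n_sims: int,
    seed: int,
    n_loci: int | None,
) -> float:
    spec = builder.build(params)
    exp = simulate_expected_sfs(spec, SimulationConfig(n_sims=n_sims, seed=seed))
    expected_snps = None
    if n_loci is not None:
        expected_snps = (
            n_loci
            * spec.mutation_rate
            * spec.locus_length
            * exp.meta["mean_total_branch_length"]
        )
    return composite_log10_likelihood(obs, exp, n_sims=n_sims,
                                      expected_snps=expected_snps)


def fit_model(
    obs: JointSFS,
    builder: ModelBuilder,
    n_runs: int = 10,
    n_sims: int = 5000,
    n_cycles: int = 10,
    seed: int = 0,
    n_points: int = 5,
    use_total_snps: bool | str = "auto",
    init: dict[str, float] | None = None,
) -> FitResult:
    """Maximize the composite likelihood of ``builder`` on ``obs``.

    Each independent run draws a log-uniform start inside the builder's
    bounds and performs ``n_cycles`` conditional-maximization cycles; within
    a cycle each free parameter in turn is moved on a shrinking symmetric
    log10 pattern of ``n_points`` candidates, all candidates of a cycle
    scored against expected spectra simulated with a shared seed (common
    random numbers, so the 1-D comparisons are not defeated by Monte Carlo
    noise).  Runs are compared at a final common-seed evaluation and the
    best run's estimates are returned.  Deterministic given ``seed``.

    ``use_total_snps`` adds the Poisson total-SNP-count term that identifies
    the absolute parameter scale; ``'auto'`` enables it when ``obs.meta``
    carries ``n_loci`` (without it, estimates are relative — only parameter
    ratios are identified by SFS proportions).

    ``init`` warm-starts half of the runs (jittered by 0.1 decades) from a
    partial parameter dict — typically the estimates of a nested simpler
    model — which rescues high-dimensional families at desk-scale budgets;
    parameters absent from ``init`` still start log-uniform.
    """
    names = builder.param_names
    if not names:
        raise ValueError("model has no free parameters")
    if use_total_snps == "auto":
        use_total_snps = "n_loci" in obs.meta
    n_loci = int(obs.meta["n_loci"]) if use_total_snps else None
    log_bounds = {
        p: (math.log10(lo), math.log10(hi)) for p, (lo, hi) in builder.bounds.items()
    }
    final_seed = _eval_seed(seed, 10_007, 10_007)
    best: tuple[float, dict] | None = None
    improved_any = False
    for run in range(n_runs):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, run])
        logp = {p: rng.uniform(*log_bounds[p]) for p in names}
        if init and run % 2 == 0:
            for p, v in init.items():
                if p in logp and v > 0:
                    lo, hi = log_bounds[p]
                    logp[p] = float(
                        np.clip(math.log10(v) + rng.normal(0, 0.1), lo, hi)
                    )
        # initial span: a quarter of each parameter's log range, shrinking to
        # ~0.05 decades by the final cycle
        span0 = {
            p: max(0.05, (log_bounds[p][1] - log_bounds[p][0]) / 4) for p in names
        }
        decay = {
            p: (0.05 / span0[p]) ** (1.0 / max(n_cycles - 1, 1)) for p in names
        }
        start_cl = None
        for cycle in range(n_cycles):
            crn = _eval_seed(seed, run, cycle)
            for p in names:
                lo, hi = log_bounds[p]
                span = span0[p] * decay[p] ** cycle
                offsets = np.linspace(-span, span, n_points)
                cand = np.clip(logp[p] + offsets, lo, hi)
                cand = np.unique(cand)
                best_val, best_cl = logp[p], -np.inf
                for x in cand:
                    trial = {q: 10 ** logp[q] for q in names}
                    trial[p] = 10 ** x
                    cl = _objective(trial, builder, obs, n_sims, crn, n_loci)
                    if cl > best_cl:
                        best_cl, best_val = cl, x
                logp[p] = best_val
                if cycle == 0 and start_cl is None:
                    start_cl = best_cl
        params = {p: 10 ** logp[p] for p in names}
        final_cl = _objective(params, builder, obs, n_sims, final_seed, n_loci)
        if start_cl is not None and final_cl > start_cl:
            improved_any = True
        if best is None or final_cl > best[0]:
            best = (final_cl, params)
    cl, params = best
    return FitResult(
        model_name=builder.name,
        estimates=params,
        log10_cl=cl,
        max_log10_cl=saturated_log10_likelihood(obs, include_total=n_loci is not None),
        k=builder.k,
        run_meta={
            "n_runs": n_runs,
            "n_sims": n_sims,
            "n_cycles": n_cycles,
            "seed": seed,
            "improved_over_start": bool(improved_any),
        },
    )


def evaluate_model(
    fit: FitResult,
    builder: ModelBuilder,
    obs_one_per_locus: JointSFS,
    n_sims_eval: int = 100_000,
    seed: int = 0,
) -> FitResult:
    """Second-step evaluation: high-precision CL on the thinned SFS, plus AIC.

    ``AIC = 2 k - 2 ln(10) * log10 CL`` (natural-log likelihood converted
    from log10).  Returns a new FitResult with ``log10_cl`` and ``aic``
    replaced by the evaluation values.
    """
    spec = builder.build(fit.estimates)
    exp = simulate_expected_sfs(
        spec, SimulationConfig(n_sims=n_sims_eval, seed=_eval_seed(seed, 777, 777))
    )
    cl = composite_log10_likelihood(obs_one_per_locus, exp, n_sims=n_sims_eval)
    aic = 2 * fit.k - 2 * LN10 * cl
    return FitResult(
        model_name=fit.model_name,
        estimates=dict(fit.estimates),
        log10_cl=cl,
        max_log10_cl=saturated_log10_likelihood(obs_one_per_locus),
        k=fit.k,
        aic=aic,
        run_meta={**fit.run_meta, "n_sims_eval": n_sims_eval, "eval_seed": seed},
    )


def rank_models(results: list[FitResult]) -> pd.DataFrame:
    """Rank by ascending AIC with ties broken by fewer parameters then name."""
    if not results:
        raise ValueError("no results to rank")
    for r in results:
        if r.aic is None:
            raise ValueError(f"model {r.model_name!r} has no AIC; evaluate it first")
    rows = sorted(results, key=lambda r: (r.aic, r.k, r.model_name))
    best_aic = rows[0].aic
    return pd.DataFrame(
        [
            {
                "model": r.model_name,
                "k": r.k,
                "log10_cl": r.log10_cl,
                "max_log10_cl": r.max_log10_cl,
                "aic": r.aic,
                "delta_aic": r.aic - best_aic,
            }
            for r in rows
        ]
    )


def parametric_bootstrap(
    best: FitResult,
    builder: ModelBuilder,
    n_loci: int,
    n_reps: int = 100,
    n_runs_per_rep: int = 10,
    n_sims: int = 50_000,
    n_cycles: int = 40,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile CIs by resimulating and refitting ``n_reps`` datasets.

    Each replicate draws a fresh observed SFS (one genealogy per locus,
    Poisson mutations) at the best estimates and refits the model with
    ``n_runs_per_rep`` short runs; the best run's estimates enter the
    percentile interval.  Replicates whose runs all fail are dropped with a
    warning count in the result.
    """
    spec = builder.build(best.estimates)
    rows = []
    n_dropped = 0
    for rep in range(n_reps):
        rep_seed = _eval_seed(seed, rep, 555_001)
        sim_obs = sample_observed_sfs(
            spec, SimulationConfig(n_loci=n_loci, seed=rep_seed, mode="sampled_sfs")
        )
        if sim_obs.total_mass(polymorphic_only=True) == 0:
            n_dropped += 1
            continue
        try:
            fit = fit_model(
                sim_obs, builder, n_runs=n_runs_per_rep, n_sims=n_sims,
                n_cycles=n_cycles, seed=rep_seed + 1,
            )
        except ValueError:
            n_dropped += 1
            continue
        rows.append({"replicate": rep, **fit.estimates})
    reps = pd.DataFrame(rows)
    if reps.empty:
        raise RuntimeError("all bootstrap replicates failed")
    params = [c for c in reps.columns if c != "replicate"]
    ci = pd.DataFrame(
        {
            "low": reps[params].quantile(0.025),
            "high": reps[params].quantile(0.975),
        }
    )
    return BootstrapResult(
        replicates=reps, ci=ci, n_requested=n_reps, n_dropped=n_dropped
    )
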