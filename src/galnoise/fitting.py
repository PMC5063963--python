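"""Staged histogram fitting and zero-free-parameter diploid prediction.

The staged protocol: stage 1 fits the haploid natural network with a
minimal free set (promoter OFF/ON transition rates, the protein action
scale, optionally the fluorescence scale); stage 2 fits the haploid
synthetic network with only the rtTA/P_TET constants plus the fluorescence
scale free, everything else carried over; stage 3 predicts diploids with
no free parameters at all (cell volume and gene copy numbers doubled).

The objective is a sum over induction conditions of the Jensen-Shannon
divergence between observed and simulated log-fluorescence histograms,
evaluated with common random numbers (the same simulation seeds for every
candidate), which makes the objective a deterministic function of the
parameters and derivative-free search tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from galnoise import networks
from galnoise.cellsim import CellCycleModel, apply_ploidy, simulate_population
from galnoise.cytometry import ExpressionSample, simulated_to_sample
from galnoise.networks import KineticParams

__all__ = [
    "FitSpec",
    "FitResult",
    "histogram_distance",
    "log_histogram",
    "fit_stage",
    "predict_diploid",
    "simulate_condition",
    "STAGE_FREE_SETS",
    "INDUCTION_DURATION_MIN",
]

#: induction duration matching the experimental protocol (22 h).
INDUCTION_DURATION_MIN = 1320.0
#: pre-induction growth simulated at zero inducer before each induction,
#: generating quenched cell-to-cell heterogeneity (the experimental
#: protocol grows cultures overnight in non-inducing media).
PREGROWTH_BURNIN_MIN = 600.0

STAGE_FREE_SETS: dict[str, frozenset[str]] = {
    "haploid-natural": frozenset({
        "k_on", "k_off_max", "k_off_basal_frac", "K80", "K4", "c_fluor",
    }),
    "haploid-synthetic": frozenset({
        "ks_rtta", "k_on_tet", "k_off_tet", "K_tet", "tet_basal_frac",
        "ks_gal80_tet", "dox", "c_fluor",
    }),
    "predict": frozenset(),
}


def simulate_condition(params: KineticParams,
                       topology: str,
                       galactose: float,
                       n_cells: int,
                       seed: int,
                       dox: float | None = None,
                       ploidy: int = 1,
                       copies: int = 1,
                       duration: float = INDUCTION_DURATION_MIN,
                       ccm: CellCycleModel | None = None,
                       beta_estradiol: float = 0.0,
                       with_tet_link: bool = False,
                       burnin: float = PREGROWTH_BURNIN_MIN) -> ExpressionSample:
    """Simulate one induction condition end to end.

    Builds the requested topology, runs the volume/cell-cycle-aware SSA
    for ``duration`` minutes, and converts reporter counts to a
    cytometry-style sample (fluorescence scale + autofluorescence +
    volume-derived scatter).  ``topology`` is ``natural``, ``synthetic``
    or ``cascade``.
    """
    if topology == "natural":
        net = networks.build_natural(params, galactose, ploidy, copies)
        net0 = networks.build_natural(params, 0.0, ploidy, copies)
    elif topology == "synthetic":
        net = networks.build_synthetic(params, galactose, dox, ploidy, copies)
        net0 = networks.build_synthetic(params, 0.0, dox, ploidy, copies)
    elif topology == "cascade":
        net = networks.build_cascade(params, beta_estradiol, with_tet_link,
                                     dox)
        net0 = networks.build_cascade(params, 0.0, with_tet_link, dox)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    if ccm is None:
        ccm = networks.default_cell_cycle(ploidy if topology != "cascade"
                                          else 1)
    endpoint = simulate_population(net, ccm, n_cells, duration, seed,
                                   extrinsic_sd=params.sigma_ext,
                                   extrinsic_tau=params.tau_ext,
                                   burnin_network=net0, burnin=burnin,
                                   metadata={
                                       "galactose": galactose,
                                       "dox": params.dox if dox is None else dox,
                                       "beta_estradiol": beta_estradiol,
                                       "topology": topology,
                                       "ploidy": ploidy,
                                       "copies": copies,
                                   })
    return simulated_to_sample(endpoint, params.c_fluor,
                               params.autofluor_log_mean,
                               params.autofluor_log_sd,
                               seed=seed + 1)


def log_histogram(fluorescence: np.ndarray,
                  edges: np.ndarray) -> np.ndarray:
    """Counts on fixed log-fluorescence bin edges (under/overflow clipped
    into the end bins so both histograms always have unit mass)."""
    x = np.clip(np.log(np.maximum(fluorescence, 1e-12)),
                edges[0], edges[-1] - 1e-12)
    counts, _ = np.histogram(x, bins=edges)
    return counts.astype(float)


def default_bin_edges(samples: Sequence[ExpressionSample],
                      n_bins: int = 64) -> np.ndarray:
    """Log-spaced bins from just below the dimmest cell to the pooled
    99.9th percentile."""
    pooled = np.concatenate([s.fluorescence for s in samples])
    lo = np.log(max(pooled.min() * 0.9, 1e-6))
    hi = np.log(np.percentile(pooled, 99.9))
    return np.linspace(lo, hi, n_bins + 1)


def histogram_distance(observed: np.ndarray, simulated: np.ndarray,
                       method: str = "js") -> float:
    """Distance between two histograms on identical bin edges.

    ``js`` (default): Jensen-Shannon divergence in nats — symmetric,
    bounded by ln 2, maximal for disjoint supports.  ``l2``: Euclidean
    distance between the normalized histograms.  ``chi2``: Pearson
    chi-square distance on the mixture denominator.
    """
    obs = np.asarray(observed, float)
    sim = np.asarray(simulated, float)
    if obs.shape != sim.shape:
        raise ValueError("histograms must share bin edges")
    if obs.sum() <= 0 or sim.sum() <= 0:
        raise ValueError("histograms must have positive mass")
    p = obs / obs.sum()
    q = sim / sim.sum()
    if method == "js":
        m = 0.5 * (p + q)
        def kl(a, b):
            mask = a > 0
            return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))
        return 0.5 * kl(p, m) + 0.5 * kl(q, m)
    if method == "l2":
        return float(np.linalg.norm(p - q))
    if method == "chi2":
        m = 0.5 * (p + q)
        mask = m > 0
        return float(0.5 * np.sum((p[mask] - q[mask]) ** 2 / m[mask]))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class FitSpec:
    """Configuration of one fitting stage.

    ``free`` maps parameter names to (low, high) bounds; the search runs
    in log space.  ``conditions`` are galactose doses; simulation seeds
    are derived once from ``seed`` and reused for every candidate
    (common random numbers).
    """

    stage: str
    free: Mapping[str, tuple[float, float]]
    conditions: Sequence[float]
    n_cells: int = 1000
    n_bins: int = 64
    dox: float | None = None
    copies: int = 1
    ploidy: int = 1
    n_starts: int = 4
    maxiter: int = 40
    seed: int = 0
    duration: float = INDUCTION_DURATION_MIN

    def __post_init__(self) -> None:
        if self.stage not in STAGE_FREE_SETS:
            raise ValueError(f"unknown stage {self.stage!r}")
        allowed = STAGE_FREE_SETS[self.stage]
        extra = set(self.free) - allowed
        if extra:
            raise ValueError(
                f"stage {self.stage!r} does not allow free parameters {extra}")
        for name, (lo, hi) in self.free.items():
            if not 0 < lo < hi:
                raise ValueError(f"bad bounds for {name!r}")


@dataclass
class FitResult:
    """Outcome of one stage: best parameters, objective, diagnostics."""

    stage: str
    params: KineticParams
    best_free: dict[str, float]
    objective: float
    per_condition: dict[float, float]
    n_evaluations: int
    trace: list[float]
    seed: int
    converged: bool


def _condition_seeds(spec: FitSpec) -> dict[float, int]:
    ss = np.random.SeedSequence([spec.seed, 0xF17])
    states = ss.generate_state(len(spec.conditions))
    return {g: int(s % (2**31)) for g, s in zip(spec.conditions, states)}


def _topology_for_stage(stage: str) -> str:
    return "synthetic" if stage == "haploid-synthetic" else "natural"


def fit_stage(spec: FitSpec,
              data: Mapping[float, ExpressionSample],
              simulator: Callable[..., ExpressionSample] | None = None,
              prior_result: FitResult | None = None,
              base_params: KineticParams | None = None) -> FitResult:
    """Minimize the summed histogram distance over the stage's free set.

    Latin-hypercube multi-start in log-parameter space followed by a
    Nelder-Mead polish from the best start; every candidate is evaluated
    with the same per-condition seeds, so the objective is deterministic.
    Stage ``haploid-synthetic`` refuses to run without a stage
    ``haploid-natural`` result (whose parameters it inherits); with an
    empty free set the fixed parameters are simply evaluated
    (prediction mode).
    """
    if spec.stage == "haploid-synthetic":
        if prior_result is None or prior_result.stage != "haploid-natural":
            raise ValueError("haploid-synthetic stage requires a completed "
                             "haploid-natural result")
        params0 = prior_result.params
    else:
        params0 = base_params if base_params is not None else (
            prior_result.params if prior_result is not None else KineticParams())
    missing = set(spec.conditions) - set(data)
    if missing:
        raise ValueError(f"data missing for conditions {sorted(missing)}")
    if simulator is None:
        simulator = simulate_condition

    edges = default_bin_edges([data[g] for g in spec.conditions], spec.n_bins)
    obs_hists = {g: log_histogram(data[g].fluorescence, edges)
                 for g in spec.conditions}
    seeds = _condition_seeds(spec)
    topology = _topology_for_stage(spec.stage)
    names = sorted(spec.free)
    lo = np.log([spec.free[n][0] for n in names])
    hi = np.log([spec.free[n][1] for n in names])

    trace: list[float] = []
    n_eval = 0

    def params_at(x: np.ndarray) -> KineticParams:
        return replace(params0, **{n: float(np.exp(v))
                                   for n, v in zip(names, x)})

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            return float(len(spec.conditions) * np.log(2.0) + 1.0)
        kp = params_at(x)
        total = 0.0
        for g in spec.conditions:
            sim = simulator(kp, topology, g, spec.n_cells, seeds[g],
                            dox=spec.dox, ploidy=spec.ploidy,
                            copies=spec.copies, duration=spec.duration)
            total += histogram_distance(obs_hists[g],
                                        log_histogram(sim.fluorescence, edges))
        if not np.isfinite(total):
            raise FloatingPointError("non-finite objective")
        n_eval += 1
        trace.append(total)
        return total

    if not names:
        val = objective(np.empty(0))
        per = _per_condition(params0, topology, spec, data, edges, seeds,
                             simulator)
        return FitResult(spec.stage, params0, {}, val, per, n_eval, trace,
                         spec.seed, converged=True)

    sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
    starts = lo + sampler.random(spec.n_starts) * (hi - lo)
    vals = [objective(x) for x in starts]
    x_best = starts[int(np.argmin(vals))]

    res = optimize.minimize(objective, x_best, method="Nelder-Mead",
                            options={"maxiter": spec.maxiter,
                                     "xatol": 0.02, "fatol": 1e-4})
    x_final = np.clip(res.x, lo, hi)
    params_best = params_at(x_final)
    best_val = objective(x_final)
    per = _per_condition(params_best, topology, spec, data, edges, seeds,
                         simulator)
    return FitResult(spec.stage, params_best,
                     {n: float(np.exp(v)) for n, v in zip(names, x_final)},
                     best_val, per, n_eval, trace, spec.seed,
                     converged=bool(res.success or res.status == 2))


def _per_condition(kp, topology, spec, data, edges, seeds, simulator):
    out = {}
    for g in spec.conditions:
        sim = simulator(kp, topology, g, spec.n_cells, seeds[g],
                        dox=spec.dox, ploidy=spec.ploidy, copies=spec.copies,
                        duration=spec.duration)
        out[g] = histogram_distance(log_histogram(data[g].fluorescence, edges),
                                    log_histogram(sim.fluorescence, edges))
    return out


def predict_diploid(haploid_fit: FitResult,
                    topology: str,
                    copies: int,
                    conditions: Sequence[float] | None = None,
                    n_cells: int = 1000,
                    seed: int = 0,
                    dox: float | None = None,
                    duration: float = INDUCTION_DURATION_MIN,
                    ) -> dict[float, ExpressionSample]:
    """Zero-free-parameter diploid prediction from a haploid fit.

    The cell volume and every gene copy count are doubled relative to the
    haploid (for the full two-copy network this is exactly
    ``cellsim.apply_ploidy`` on the haploid network; the network-hemizygous
    diploid keeps a single copy of the regulatory genes in the doubled
    cell).  Simulates 22 h inductions at the requested galactose doses and
    returns samples ready for the cytometry pipeline.
    """
    if copies not in (1, 2):
        raise ValueError("copies must be 1 or 2")
    if topology not in ("natural", "synthetic"):
        raise ValueError("topology must be natural or synthetic")
    params = haploid_fit.params
    if conditions is None:
        conditions = [0.0, 0.005, 0.01, 0.02, 0.03, 0.05, 0.075, 0.1,
                      0.15, 0.25, 0.5]
    ss = np.random.SeedSequence([seed, 0xD1B])
    seeds = {g: int(s % (2**31))
             for g, s in zip(conditions, ss.generate_state(len(conditions)))}
    out = {}
    for g in conditions:
        if copies == 2:
            # diploid homozygote == apply_ploidy(haploid one-copy network)
            if topology == "natural":
                net1 = networks.build_natural(params, g, ploidy=1, copies=1)
            else:
                net1 = networks.build_synthetic(params, g, dox, ploidy=1,
                                                copies=1)
            net, ccm = apply_ploidy(net1, networks.default_cell_cycle(1), 2)
        else:
            if topology == "natural":
                net = networks.build_natural(params, g, ploidy=2, copies=1)
            else:
                net = networks.build_synthetic(params, g, dox, ploidy=2,
                                               copies=1)
            ccm = networks.default_cell_cycle(2)
        endpoint = simulate_population(net, ccm, n_cells, duration, seeds[g],
                                       extrinsic_sd=params.sigma_ext,
                                       extrinsic_tau=params.tau_ext,
                                       metadata={"galactose": g,
                                                 "topology": topology,
                                                 "ploidy": 2,
                                                 "copies": copies})
        out[g] = simulated_to_sample(endpoint, params.c_fluor,
                                     params.autofluor_log_mean,
                                     params.autofluor_log_sd,
                                     seed=seeds[g] + 1)
    return out
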