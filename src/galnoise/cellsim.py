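"""Volume- and cell-cycle-aware stochastic simulation engine.

An exact-SSA-style kernel whose propensities depend on the current cell
volume and on per-copy promoter states, interleaved in correct time order
with two deterministic cell-cycle events: DNA replication (all gene copy
counts double when the cycle phase crosses the S-phase point) and cell
division (volume is split, molecules are partitioned binomially, one
daughter is followed).

Volume is treated as constant between successive firings; the waiting time
is truncated at ``doubling_time / volume_update_steps`` (advance without
firing), which by the memorylessness of the exponential is statistically
identical to adding a null "clock" reaction and bounds propensity staleness
from volume growth.  With growth disabled (``doubling_time = inf``) the cap
never binds and the kernel is a textbook Gillespie SSA.

Reaction propensities are mass-action forms scaled by a volume power, each
optionally modulated by a Hill function of a regulator species'
concentration::

    a = k * base(counts, locus) * V**vexp * f(x),
    f(x) = basal + (1 - basal) * x**n / (x**n + K**n),  x = counts[reg] / V

Base forms: constant, unimolecular, bimolecular (``vexp = -1``), and
per-ON-copy / per-OFF-copy / per-total-copy of a gene locus.  Promoter
switching reactions are per-copy reactions that change the locus's ON-copy
count by +/-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from numba import njit

__all__ = [
    "CellCycleModel",
    "Reaction",
    "GeneLocus",
    "ReactionNetwork",
    "CellState",
    "EndpointSample",
    "step_cell",
    "simulate_population",
    "apply_ploidy",
]

# propensity base forms
CONST, UNI, BI, PER_ON, PER_OFF, PER_TOT = range(6)
_BASE_CODES = {
    "const": CONST, "uni": UNI, "bi": BI,
    "per_on": PER_ON, "per_off": PER_OFF, "per_tot": PER_TOT,
}


@dataclass(frozen=True)
class CellCycleModel:
    """Deterministic cell-cycle scaffold around the stochastic kernel.

    doubling_time
        Cycle length in minutes; ``inf`` disables growth and division.
    birth_volume
        Volume at cycle start, in femtolitres.
    growth_law
        ``exponential``: V = V_b * 2**phase; ``linear``: V = V_b * (1+phase).
        Both reach 2x the birth volume at division.
    s_phase_fraction
        Cycle fraction at which every gene locus doubles its copy count
        (instantaneous S phase).
    partition_rule
        ``binomial_symmetric``: molecules binomial(p=1/2), volume halved.
        ``volume_proportional``: the followed daughter keeps
        ``daughter_fraction`` of the volume and molecules binomial with the
        same probability.
    cycle_length_cv
        Cell-to-cell variability of individual cycle lengths: each cycle's
        duration is the doubling time times a log-normal factor with this
        coefficient of variation.  Randomized cycle lengths desynchronize
        DNA replication from cell size, so the population carries genuine
        gene-dosage noise at harvest (zero restores a strictly periodic
        cycle).
    volume_update_steps
        The SSA waiting time is capped at doubling_time / this value,
        bounding the volume change between propensity evaluations.
    """

    doubling_time: float = 100.0
    birth_volume: float = 30.0
    growth_law: str = "exponential"
    s_phase_fraction: float = 0.4
    partition_rule: str = "binomial_symmetric"
    daughter_fraction: float = 0.5
    cycle_length_cv: float = 0.2
    s_phase_jitter: float = 0.15
    volume_update_steps: int = 200

    def __post_init__(self) -> None:
        if self.growth_law not in ("exponential", "linear"):
            raise ValueError(f"unknown growth law {self.growth_law!r}")
        if self.partition_rule not in ("binomial_symmetric", "volume_proportional"):
            raise ValueError(f"unknown partition rule {self.partition_rule!r}")
        if not (0.0 < self.s_phase_fraction < 1.0):
            raise ValueError("s_phase_fraction must be in (0, 1)")
        if not self.birth_volume > 0:
            raise ValueError("birth_volume must be positive")
        if not (0.0 < self.daughter_fraction < 1.0):
            raise ValueError("daughter_fraction must be in (0, 1)")
        if self.cycle_length_cv < 0 or self.s_phase_jitter < 0:
            raise ValueError("cycle randomness parameters must be >= 0")

    @property
    def molecule_partition_p(self) -> float:
        if self.partition_rule == "binomial_symmetric":
            return 0.5
        return self.daughter_fraction

    @property
    def retained_volume_fraction(self) -> float:
        if self.partition_rule == "binomial_symmetric":
            return 0.5
        return self.daughter_fraction


@dataclass(frozen=True)
class Reaction:
    """One reaction channel.

    ``stoich`` maps species name -> integer change on firing; ``dlocus``
    is the change to the locus's ON-copy count (promoter switching).
    """

    name: str
    base: str
    k: float
    s1: str | None = None
    s2: str | None = None
    locus: str | None = None
    vexp: float = 0.0
    reg: str | None = None
    reg_K: float = 1.0
    reg_n: float = 1.0
    reg_basal: float = 0.0
    stoich: Mapping[str, int] = field(default_factory=dict)
    dlocus: int = 0
    #: synthesis reactions scale with the cell's global expression capacity
    #: (the stochastic counterpart of a global dosage perturbation)
    extrinsic: bool = False

    def __post_init__(self) -> None:
        if self.base not in _BASE_CODES:
            raise ValueError(f"unknown propensity base {self.base!r}")
        if self.k < 0:
            raise ValueError(f"rate constant of {self.name!r} must be >= 0")
        if self.base in ("per_on", "per_off", "per_tot") and self.locus is None:
            raise ValueError(f"reaction {self.name!r} needs a locus")
        if self.base in ("uni", "bi") and self.s1 is None:
            raise ValueError(f"reaction {self.name!r} needs reactant s1")
        if self.base == "bi" and self.s2 is None:
            raise ValueError(f"reaction {self.name!r} needs reactant s2")


@dataclass(frozen=True)
class GeneLocus:
    """A promoter with an integer copy count and a per-copy ON/OFF state."""

    name: str
    copies: int = 1
    init_on: int = 0

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not 0 <= self.init_on <= self.copies:
            raise ValueError("init_on must be within [0, copies]")


@dataclass
class ReactionNetwork:
    """Species, gene loci, and volume-aware reactions."""

    species: list[str]
    loci: list[GeneLocus]
    reactions: list[Reaction]
    init_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        locus_names = [l.name for l in self.loci]
        if len(set(locus_names)) != len(locus_names):
            raise ValueError("duplicate locus names")
        for r in self.reactions:
            for s in (r.s1, r.s2, r.reg):
                if s is not None and s not in self.species:
                    raise ValueError(f"reaction {r.name!r}: unknown species {s!r}")
            if r.locus is not None and r.locus not in locus_names:
                raise ValueError(f"reaction {r.name!r}: unknown locus {r.locus!r}")
            for s in r.stoich:
                if s not in self.species:
                    raise ValueError(f"reaction {r.name!r}: unknown species {s!r}")
        for s, n in self.init_counts.items():
            if s not in self.species:
                raise ValueError(f"unknown init species {s!r}")
            if n < 0:
                raise ValueError("initial counts must be nonnegative")

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def locus_index(self, name: str) -> int:
        return [l.name for l in self.loci].index(name)

    def compile(self):
        """Pack the network into flat arrays for the jitted kernel."""
        nsp, nr = len(self.species), len(self.reactions)
        sidx = {s: i for i, s in enumerate(self.species)}
        lidx = {l.name: i for i, l in enumerate(self.loci)}
        base = np.empty(nr, np.int64)
        k = np.empty(nr, np.float64)
        i1 = np.full(nr, -1, np.int64)
        i2 = np.full(nr, -1, np.int64)
        loc = np.full(nr, -1, np.int64)
        vexp = np.zeros(nr, np.float64)
        reg = np.full(nr, -1, np.int64)
        regK = np.ones(nr, np.float64)
        regn = np.ones(nr, np.float64)
        regb = np.zeros(nr, np.float64)
        S = np.zeros((nr, nsp), np.int64)
        dloc = np.zeros(nr, np.int64)
        ext = np.zeros(nr, np.int64)
        for j, r in enumerate(self.reactions):
            base[j] = _BASE_CODES[r.base]
            k[j] = r.k
            if r.s1 is not None:
                i1[j] = sidx[r.s1]
            if r.s2 is not None:
                i2[j] = sidx[r.s2]
            if r.locus is not None:
                loc[j] = lidx[r.locus]
            vexp[j] = r.vexp
            if r.reg is not None:
                reg[j] = sidx[r.reg]
                regK[j] = r.reg_K
                regn[j] = r.reg_n
                regb[j] = r.reg_basal
            for s, d in r.stoich.items():
                S[j, sidx[s]] = d
            dloc[j] = r.dlocus
            ext[j] = 1 if r.extrinsic else 0
        return (base, k, i1, i2, loc, vexp, reg, regK, regn, regb, S, dloc,
                ext)

    def initial_count_vector(self) -> np.ndarray:
        out = np.zeros(len(self.species), np.int64)
        for s, n in self.init_counts.items():
            out[self.species.index(s)] = n
        return out


@dataclass
class CellState:
    """One cell: volume, cycle position, molecule counts, promoter states."""

    volume: float
    phase: float
    counts: dict[str, int]
    promoter_on: dict[str, int]
    replicated: bool = False
    birth_volume: float | None = None
    seed: int = 0
    #: global expression-capacity factor (scales synthesis reactions)
    capacity: float = 1.0

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError("volume must be positive")
        if not 0.0 <= self.phase < 1.0:
            raise ValueError("cycle phase must be in [0, 1)")


@dataclass
class EndpointSample:
    """Endpoint snapshot of a simulated population (one row per cell)."""

    counts: np.ndarray           # (n_cells, n_species)
    species: list[str]
    volumes: np.ndarray          # (n_cells,)
    phases: np.ndarray
    locus_copies: np.ndarray     # (n_cells, n_loci) total copies at harvest
    locus_names: list[str]
    capacities: np.ndarray | None = None  # per-cell extrinsic factors
    metadata: dict = field(default_factory=dict)

    def species_counts(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=self.species)
        df["volume_fl"] = self.volumes
        df["cycle_phase"] = self.phases
        for key, val in self.metadata.items():
            if np.isscalar(val) or isinstance(val, str):
                df[key] = val
        return df


# ---------------------------------------------------------------------------
# jitted kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _volume(vb, phase, exponential):
    if exponential:
        return vb * 2.0 ** phase
    return vb * (1.0 + phase)


@njit(cache=True)
def _cycle_draws(T, sfrac, ccv, sjit):
    """Draw one cycle's length and S-phase point."""
    Tc = T
    if ccv > 0.0 and T < np.inf:
        sig = np.sqrt(np.log(1.0 + ccv * ccv))
        Tc = T * np.exp(sig * np.random.standard_normal() - 0.5 * sig * sig)
    sc = sfrac
    if sjit > 0.0:
        sc = sfrac + (np.random.random() - 0.5) * 2.0 * sjit
        sc = min(max(sc, 0.05), 0.95)
    return Tc, sc


@njit(cache=True)
def _advance(counts, non, ntot, state, t_end,
             T, exponential, sfrac, dtmax, pmol, vfrac, ccv, sjit,
             base, k, i1, i2, loc, vexp, reg, regK, regn, regb, S, dloc,
             ext, ext_state, ext_sd, ext_tau):
    """Advance one cell to t_end.

    state = [t, phase, replicated, birth_vol, cycle_T, cycle_sfrac];
    ext_state = [log capacity], an Ornstein-Uhlenbeck process with
    stationary sd ``ext_sd`` and correlation time ``ext_tau`` that scales
    every synthesis (``ext``-flagged) propensity.  Each cycle's length and
    S-phase point are randomized (``ccv``, ``sjit``), desynchronizing the
    gene-dosage state from cell size.

    Returns 0 on success, 1 if a count went negative (a modelling error).
    """
    t = state[0]
    phase = state[1]
    rep = state[2] > 0.5
    vb = state[3]
    Tc = state[4]
    sc = state[5]
    nr = base.shape[0]
    nsp = counts.shape[0]
    nl = non.shape[0]
    a = np.empty(nr, np.float64)
    x_ext = ext_state[0]
    have_ext = ext_sd > 0.0

    while t < t_end - 1e-9:
        V = _volume(vb, phase, exponential)
        xi = np.exp(x_ext) if have_ext else 1.0
        a0 = 0.0
        for j in range(nr):
            b = base[j]
            if b == 0:
                aj = k[j]
            elif b == 1:
                aj = k[j] * counts[i1[j]]
            elif b == 2:
                aj = k[j] * counts[i1[j]] * counts[i2[j]]
            elif b == 3:
                aj = k[j] * non[loc[j]]
            elif b == 4:
                aj = k[j] * (ntot[loc[j]] - non[loc[j]])
            else:
                aj = k[j] * ntot[loc[j]]
            if aj > 0.0:
                if ext[j] == 1:
                    aj *= xi
                if vexp[j] != 0.0:
                    aj *= V ** vexp[j]
                rj = reg[j]
                if rj >= 0:
                    # regn > 0: increasing Hill in x; regn < 0: decreasing
                    # (x^n/(x^n+K^n) with negative n equals K^m/(K^m+x^m))
                    x = counts[rj] / V
                    if x <= 0.0:
                        hillv = 1.0 if regn[j] < 0.0 else 0.0
                    else:
                        xn = x ** regn[j]
                        hillv = xn / (xn + regK[j] ** regn[j])
                    aj *= regb[j] + (1.0 - regb[j]) * hillv
            a[j] = aj
            a0 += aj

        # next deterministic event
        if T == np.inf:
            t_det = np.inf
        elif not rep:
            t_det = t + (sc - phase) * Tc
        else:
            t_det = t + (1.0 - phase) * Tc
        t_stop = t_det if t_det < t_end else t_end

        if a0 <= 0.0:
            dt = np.inf
        else:
            dt = -np.log(np.random.random()) / a0
        fire = True
        if dt > dtmax:
            dt = dtmax
            fire = False

        if t + dt >= t_stop:
            if have_ext and t_stop > t:
                decay = np.exp(-(t_stop - t) / ext_tau)
                x_ext = (x_ext * decay + ext_sd
                         * np.sqrt(1.0 - decay * decay)
                         * np.random.standard_normal())
            if T < np.inf:
                phase += (t_stop - t) / Tc
            t = t_stop
            if t >= t_end - 1e-9:
                break
            if not rep and phase >= sc - 1e-12:
                for l in range(nl):
                    non[l] *= 2
                    ntot[l] *= 2
                rep = True
            elif phase >= 1.0 - 1e-12:
                for i in range(nsp):
                    if counts[i] > 0:
                        counts[i] = np.random.binomial(counts[i], pmol)
                for l in range(nl):
                    keep = ntot[l] // 2
                    on_rem = non[l]
                    tot_rem = ntot[l]
                    kon = 0
                    for _ in range(keep):
                        if np.random.random() * tot_rem < on_rem:
                            kon += 1
                            on_rem -= 1
                        tot_rem -= 1
                    non[l] = kon
                    ntot[l] = keep
                vb = 2.0 * vb * vfrac
                phase = 0.0
                rep = False
                Tc, sc = _cycle_draws(T, sfrac, ccv, sjit)
            continue

        if have_ext:
            decay = np.exp(-dt / ext_tau)
            x_ext = (x_ext * decay + ext_sd
                     * np.sqrt(1.0 - decay * decay)
                     * np.random.standard_normal())
        t += dt
        if T < np.inf:
            phase += dt / Tc
        if fire:
            target = np.random.random() * a0
            acc = 0.0
            r = nr - 1
            for j in range(nr):
                acc += a[j]
                if target < acc:
                    r = j
                    break
            for i in range(nsp):
                counts[i] += S[r, i]
                if counts[i] < 0:
                    return 1
            if dloc[r] != 0:
                lr = loc[r]
                non[lr] += dloc[r]
                if non[lr] < 0 or non[lr] > ntot[lr]:
                    return 1

    state[0] = t
    state[1] = phase
    state[2] = 1.0 if rep else 0.0
    state[3] = vb
    state[4] = Tc
    state[5] = sc
    ext_state[0] = x_ext
    return 0


@njit(cache=True)
def _run_population(compiled_base, compiled_k, i1, i2, loc, vexp,
                    reg, regK, regn, regb, S, dloc, ext,
                    init_counts, locus_copies0, locus_on0,
                    T, exponential, sfrac, dtmax, pmol, vfrac, ccv, sjit, vb0,
                    duration, burnin, k_burn, ext_sd, ext_tau, seeds,
                    out_counts, out_vol, out_phase, out_copies, out_xi):
    n_cells = seeds.shape[0]
    nsp = init_counts.shape[0]
    nl = locus_copies0.shape[0]
    status = 0
    for c in range(n_cells):
        np.random.seed(seeds[c])
        phase0 = np.random.random()
        ext_state = np.zeros(1, np.float64)
        if ext_sd > 0.0:
            # stationary draw of the log-capacity OU process
            ext_state[0] = ext_sd * np.random.standard_normal()
        Tc, sc = _cycle_draws(T, sfrac, ccv, sjit)
        counts = init_counts.copy()
        non = locus_on0.copy()
        ntot = locus_copies0.copy()
        rep = phase0 >= sc and T < np.inf
        if rep:
            for l in range(nl):
                non[l] *= 2
                ntot[l] *= 2
        state = np.empty(6, np.float64)
        state[0] = 0.0
        state[1] = phase0 if T < np.inf else 0.0
        state[2] = 1.0 if rep else 0.0
        state[3] = vb0
        state[4] = Tc
        state[5] = sc
        rc = 0
        if burnin > 0.0:
            # pre-induction growth under the burn-in rate constants
            rc = _advance(counts, non, ntot, state, burnin,
                          T, exponential, sfrac, dtmax, pmol, vfrac,
                          ccv, sjit,
                          compiled_base, k_burn, i1, i2, loc, vexp,
                          reg, regK, regn, regb, S, dloc,
                          ext, ext_state, ext_sd, ext_tau)
            state[0] = 0.0
        if rc == 0:
            rc = _advance(counts, non, ntot, state, duration,
                          T, exponential, sfrac, dtmax, pmol, vfrac,
                          ccv, sjit,
                          compiled_base, compiled_k, i1, i2, loc, vexp,
                          reg, regK, regn, regb, S, dloc,
                          ext, ext_state, ext_sd, ext_tau)
        if rc != 0:
            status = rc
        for i in range(nsp):
            out_counts[c, i] = counts[i]
        out_vol[c] = _volume(state[3], state[1], exponential)
        out_phase[c] = state[1]
        for l in range(nl):
            out_copies[c, l] = ntot[l]
        out_xi[c] = np.exp(ext_state[0])
    return status


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _kernel_args(ccm: CellCycleModel):
    T = float(ccm.doubling_time)
    dtmax = T / ccm.volume_update_steps if np.isfinite(T) else np.inf
    return (T, ccm.growth_law == "exponential", ccm.s_phase_fraction,
            dtmax, ccm.molecule_partition_p, ccm.retained_volume_fraction,
            ccm.cycle_length_cv, ccm.s_phase_jitter)


def step_cell(cell: CellState, network: ReactionNetwork,
              ccm: CellCycleModel, horizon: float) -> CellState:
    """Advance a single cell by ``horizon`` minutes.

    Interleaves SSA firings with replication and division in correct time
    order; the returned state carries a freshly drawn seed so that repeated
    calls continue the cell's private random stream.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    base, k, i1, i2, loc, vexp, reg, regK, regn, regb, S, dloc, ext = \
        network.compile()
    counts = np.array([cell.counts.get(s, 0) for s in network.species], np.int64)
    non = np.array([cell.promoter_on.get(l.name, 0) for l in network.loci], np.int64)
    mult = 2 if cell.replicated else 1
    ntot = np.array([l.copies * mult for l in network.loci], np.int64)
    vb = cell.birth_volume
    if vb is None:
        if ccm.growth_law == "exponential":
            vb = cell.volume / 2.0 ** cell.phase
        else:
            vb = cell.volume / (1.0 + cell.phase)
    T, expo, sfrac, dtmax, pmol, vfrac, ccv, sjit = _kernel_args(ccm)
    state = np.array([0.0, cell.phase, 1.0 if cell.replicated else 0.0, vb,
                      T, sfrac])
    _seed_rng(np.uint32(cell.seed))
    # a fixed capacity acts as a frozen (infinite-correlation-time) factor
    ext_state = np.array([np.log(cell.capacity)], np.float64)
    ext_sd = 0.0 if cell.capacity == 1.0 else 1e-30
    rc = _advance(counts, non, ntot, state, float(horizon),
                  T, expo, sfrac, dtmax, pmol, vfrac, ccv, sjit,
                  base, k, i1, i2, loc, vexp, reg, regK, regn, regb, S, dloc,
                  ext, ext_state, ext_sd, np.inf)
    if rc != 0:
        raise RuntimeError("negative molecule count: inconsistent stoichiometry")
    rep = state[2] > 0.5
    new_seed = int(np.random.default_rng([cell.seed, 0x5EED]).integers(2**31))
    return CellState(
        volume=float(_volume(state[3], state[1], ccm.growth_law == "exponential")),
        phase=float(state[1]) % 1.0,
        counts={s: int(c) for s, c in zip(network.species, counts)},
        promoter_on={l.name: int(n) for l, n in zip(network.loci, non)},
        replicated=bool(rep),
        birth_volume=float(state[3]),
        seed=new_seed,
    )


def simulate_population(network: ReactionNetwork | Callable[[], ReactionNetwork],
                        ccm: CellCycleModel,
                        n_cells: int,
                        duration: float,
                        seed: int,
                        extrinsic_sd: float = 0.0,
                        extrinsic_tau: float = 150.0,
                        burnin_network: "ReactionNetwork | None" = None,
                        burnin: float = 0.0,
                        metadata: dict | None = None) -> EndpointSample:
    """Simulate independent single-cell lineages and harvest at ``duration``.

    Each cell starts at a uniformly random cycle phase with the
    growth-law-consistent volume and the network's initial counts
    (asynchronous uninduced culture), evolves by the volume-aware SSA with
    replication/division events, and one daughter is retained at each
    division.  ``extrinsic_sd`` > 0 gives every lineage a global
    expression-capacity factor scaling all synthesis reactions — the
    stochastic counterpart of an effective network-dosage perturbation
    (ribosomes, polymerase, transcription machinery).  Its log follows a
    stationary Ornstein-Uhlenbeck process with sd ``extrinsic_sd`` and
    correlation time ``extrinsic_tau`` minutes.  A ``burnin_network``
    (same species/reactions, different rate constants — e.g. the same
    topology at zero galactose) is simulated for ``burnin`` minutes first,
    so the induction starts from the quenched cell-to-cell heterogeneity
    of a pre-growth culture instead of identical initial conditions.
    Fully reproducible for a given ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    if callable(network) and not isinstance(network, ReactionNetwork):
        network = network()
    compiled = network.compile()
    nsp = len(network.species)
    nl = len(network.loci)
    init_counts = network.initial_count_vector()
    copies0 = np.array([l.copies for l in network.loci], np.int64)
    on0 = np.array([l.init_on for l in network.loci], np.int64)
    seeds = np.random.SeedSequence(seed).generate_state(n_cells).astype(np.uint32)

    out_counts = np.empty((n_cells, nsp), np.int64)
    out_vol = np.empty(n_cells, np.float64)
    out_phase = np.empty(n_cells, np.float64)
    out_copies = np.empty((n_cells, nl), np.int64)
    out_xi = np.ones(n_cells, np.float64)

    T, expo, sfrac, dtmax, pmol, vfrac, ccv, sjit = _kernel_args(ccm)
    if duration == 0:
        # endpoint equals the initial condition (with randomized phases)
        rng = np.random.default_rng(seed)
        phases = rng.random(n_cells) if np.isfinite(T) else np.zeros(n_cells)
        for c in range(n_cells):
            out_counts[c] = init_counts
            mult = 2 if (phases[c] >= sfrac and np.isfinite(T)) else 1
            out_copies[c] = copies0 * mult
            out_vol[c] = _volume(ccm.birth_volume, phases[c], expo)
        out_phase[:] = phases
    else:
        if burnin_network is not None and burnin > 0:
            if (burnin_network.species != network.species
                    or len(burnin_network.reactions) != len(network.reactions)):
                raise ValueError("burn-in network must share the induction "
                                 "network's structure")
            k_burn = burnin_network.compile()[1]
        else:
            k_burn = compiled[1]
            burnin = 0.0
        rc = _run_population(*compiled, init_counts, copies0, on0,
                             T, expo, sfrac, dtmax, pmol, vfrac, ccv, sjit,
                             ccm.birth_volume, float(duration),
                             float(burnin), k_burn,
                             float(extrinsic_sd), float(extrinsic_tau), seeds,
                             out_counts, out_vol, out_phase, out_copies,
                             out_xi)
        if rc != 0:
            raise RuntimeError("negative molecule count during simulation")

    meta = dict(metadata or {})
    meta.setdefault("seed", seed)
    meta.setdefault("duration_min", duration)
    meta.setdefault("extrinsic_sd", extrinsic_sd)
    return EndpointSample(out_counts, list(network.species), out_vol, out_phase,
                          out_copies, [l.name for l in network.loci], out_xi,
                          meta)


def apply_ploidy(network: ReactionNetwork, cell0: CellState | CellCycleModel,
                 ploidy_factor: int):
    """Scale gene copy counts and cell volume for a ploidy change.

    Multiplies every locus copy count and the birth/initial volume by
    ``ploidy_factor`` (1 or 2); no rate constant changes.  ``cell0`` may be
    a :class:`CellState` or a :class:`CellCycleModel` (whose birth volume
    is scaled).  Returns the scaled ``(network, cell0)`` pair.
    """
    if ploidy_factor not in (1, 2):
        raise ValueError("ploidy_factor must be 1 or 2")
    if ploidy_factor == 1:
        return network, cell0
    loci = [replace(l, copies=l.copies * ploidy_factor,
                    init_on=l.init_on * ploidy_factor) for l in network.loci]
    net2 = ReactionNetwork(list(network.species), loci, list(network.reactions),
                           dict(network.init_counts))
    if isinstance(cell0, CellCycleModel):
        scaled = replace(cell0, birth_volume=cell0.birth_volume * ploidy_factor)
    else:
        scaled = replace(
            cell0,
            volume=cell0.volume * ploidy_factor,
            birth_volume=None if cell0.birth_volume is None
            else cell0.birth_volume * ploidy_factor,
        )
    return net2, scaled
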