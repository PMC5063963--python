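"""Concrete reaction networks: natural GAL, synthetic rtTA/P_TET GAL, cascade.

Shared kinetic scheme
---------------------
Gal4 is expressed constitutively.  Every regulated promoter copy switches
ON at a rate increasing with the free-Gal4 concentration and OFF at a rate
increasing with the free-Gal80 concentration (Hill coefficient 2); an
activity-independent basal synthesis from OFF copies makes the uninduced
state leaky enough to respond to galactose.  Internal galactose is a
deterministic signal proportional to the external dose and to a saturating
function of the Gal2 transporter level.  Galactose converts Gal3 (and,
40-fold more weakly, Gal1) into active inducers that sequester free Gal80
with 1-to-1 stoichiometry; free Gal80 is what the promoters see, so the
inducer/repressor balance closes both the positive (Gal3/Gal1/Gal2) and
negative (Gal80) feedback loops.

The synthetic topology removes the Gal4-regulated GAL80 gene and produces
Gal80 from a TET promoter whose ON-switching rate is a Hill function
(coefficient 2, one per rtTA operator) of rtTA * doxycycline, with rtTA
expressed from the Gal80 promoter — the negative-feedback path from
activity to Gal80 production is preserved but now passes through the
dose-dependent rtTA/P_TET link.

Defaults were calibrated once against the deterministic steady-state model
and small pilot simulations to reproduce the documented qualitative
regimes (OFF at zero galactose, bimodal induction over 0-0.5% galactose,
dosage compensation of the natural topology); each parameter class carries
a provenance tag.  All values are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from galnoise.cellsim import (
    CellCycleModel,
    GeneLocus,
    Reaction,
    ReactionNetwork,
)

__all__ = [
    "KineticParams",
    "build_natural",
    "build_synthetic",
    "build_cascade",
    "default_cell_cycle",
    "structural_diff",
]

#: genes whose loci constitute "one copy of the network" (network dosage);
#: the reporter locus is not part of the network dosage.
NETWORK_GENES_NATURAL = ("P_GAL4", "P_GAL3", "P_GAL1", "P_GAL2", "P_GAL80")
NETWORK_GENES_SYNTHETIC = ("P_GAL4", "P_GAL3", "P_GAL1", "P_GAL2",
                           "P_GAL80_rtTA", "P_TET_GAL80")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants of the stochastic networks.

    Rates are per minute, concentrations in molecules per femtolitre.
    ``provenance`` tags each parameter class: scale-type constants are
    ``fixed_literature`` analogues, promoter-transition and action-scale
    constants are the stage-1 free set (``fit_haploid_natural``), and the
    rtTA/P_TET constants plus the fluorescence scale are the stage-2 free
    set (``fit_haploid_synthetic``).
    """

    # promoter switching (regulated Gal4-binding promoters)
    k_on: float = 0.3             # ON rate per OFF copy, free Gal4 abundant
    k_on_basal_frac: float = 0.02    # residual ON rate under full repression
    k_off_max: float = 1.2        # OFF rate per ON copy at saturating Gal80
    k_off_basal_frac: float = 0.02   # basal OFF rate fraction of k_off_max
    K80: float = 0.15             # free-Gal80 conc half-repression
    n80: float = 2.0
    # synthesis per promoter copy (protein per minute; mRNA layer folded in)
    ks_gal4: float = 0.25
    ks_gal3: float = 1.4
    ks_gal1: float = 1.4
    ks_gal2: float = 0.4
    ks_gal80: float = 0.4
    ks_yfp: float = 1.2
    basal_frac: float = 0.08      # OFF-copy synthesis relative to ON-copy
    gal80_basal_frac: float = 0.25  # Gal80-promoter basal (repressor excess
                                    # in the uninduced state; also rtTA's)
    # decay (dilution by growth/division is handled by the cell cycle);
    # the reporter has its own faster turnover so it tracks activity
    delta_p: float = 0.003
    delta_yfp: float = 0.003
    # galactose activation of inducers
    k_gact: float = 0.3           # per (% galactose) per minute, full import
    k_gdeact: float = 0.02
    w1: float = 1.0 / 40.0        # Gal1 is a ~40-fold weaker inducer
    import_c0: float = 0.3        # Gal2-independent import fraction
    import_c2: float = 0.7        # Gal2-dependent import fraction
    K2: float = 0.5               # Gal2 conc half-saturation of import
    # 1-to-1 sequestration of Gal80 by active inducers
    k_seq: float = 0.5            # fl per molecule per minute (bimolecular)
    k_unseq: float = 0.0005
    # rtTA / P_TET link (synthetic topology; two rtTA operators -> Hill 2)
    ks_rtta: float = 0.2
    k_on_tet: float = 0.15
    k_off_tet: float = 0.3
    K_tet: float = 0.6            # rtTA conc * dox at half-maximal switching
    n_tet: float = 2.0
    tet_basal_frac: float = 0.05
    ks_gal80_tet: float = 1.3
    dox: float = 1.8              # matched to the natural network's
                                  # activity in its linear-response regime
    # beta-estradiol cascade
    ks_lexa: float = 0.25
    k_on_lexa: float = 0.5
    k_off_lexa: float = 1.0
    K_lexa: float = 0.4           # active-LexA conc half-activation
    n_lexa: float = 2.0
    K_estradiol: float = 10.0     # nM half-activation of LexA-ER-AD
    ks_yfp_cascade: float = 1.0
    dox_cascade: float = 1.2
    # cell-to-cell extrinsic variability in galactose uptake/signalling:
    # a log-normal factor on the inducer-activation rates, quasi-static per
    # lineage (transporter and signalling-capacity heterogeneity); spreads
    # the per-cell induction threshold across the population
    sigma_ext: float = 0.5
    tau_ext: float = 2000.0       # correlation time (min); >> induction
    # fluorescence bridge (flow-cytometry scale)
    c_fluor: float = 20.0         # a.u. per YFP molecule
    autofluor_log_mean: float = float(np.log(300.0))
    autofluor_log_sd: float = 0.25
    provenance: dict = field(default_factory=lambda: {
        "promoter_switching": "fit_haploid_natural",
        "action_scales": "fit_haploid_natural",
        "synthesis_decay_scales": "fixed_literature",
        "galactose_import": "fixed_literature",
        "rtta_tet": "fit_haploid_synthetic",
        "c_fluor": "fit_haploid_synthetic",
    })

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off_max", "K80", "ks_gal4", "ks_gal3",
                     "ks_gal1", "ks_gal2", "ks_gal80", "ks_yfp", "k_gdeact",
                     "k_seq", "K_tet", "K_lexa", "c_fluor", "delta_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.w1 <= 1:
            raise ValueError("w1 must be in [0, 1] (Gal1 the weaker inducer)")
        if not 0 <= self.basal_frac <= 1:
            raise ValueError("basal_frac must be in [0, 1]")


def default_cell_cycle(ploidy: int = 1) -> CellCycleModel:
    """Default cell-cycle model: 100 min doubling, 30 fl haploid birth
    volume; diploids are twice the volume."""
    return CellCycleModel(doubling_time=100.0, birth_volume=30.0 * ploidy)


def _regulated_locus_reactions(p: KineticParams, locus: str) -> list[Reaction]:
    """ON/OFF switching of a Gal4-binding promoter.

    Gal4 is constitutive, so the *free* (Gal80-unoccupied) Gal4 level
    tracks the free-Gal80 concentration: the ON rate falls and the OFF
    rate rises with free Gal80 (both Hill coefficient ``n80``), each with
    a small Gal80-independent floor.  Regulating both transitions gives
    the wide, clean ON/OFF separation of the GAL bistable switch.
    """
    return [
        Reaction(f"{locus}:on", "per_off", p.k_on, locus=locus, dlocus=+1,
                 reg="Gal80", reg_K=p.K80, reg_n=-p.n80,
                 reg_basal=p.k_on_basal_frac),
        Reaction(f"{locus}:off", "per_on", p.k_off_max, locus=locus, dlocus=-1,
                 reg="Gal80", reg_K=p.K80, reg_n=p.n80,
                 reg_basal=p.k_off_basal_frac),
    ]


def _expression_reactions(p: KineticParams, locus: str, product: str,
                          rate: float,
                          basal_frac: float | None = None) -> list[Reaction]:
    """Effective protein synthesis from ON copies plus OFF-copy basal."""
    basal = p.basal_frac if basal_frac is None else basal_frac
    return [
        Reaction(f"{locus}:syn", "per_on", rate, locus=locus,
                 stoich={product: 1}),
        Reaction(f"{locus}:syn_basal", "per_off", rate * basal,
                 locus=locus, stoich={product: 1}),
    ]


def _decay(p: KineticParams, species: Iterable[str]) -> list[Reaction]:
    return [Reaction(f"{s}:decay", "uni", p.delta_p, s1=s, stoich={s: -1})
            for s in species]


def _inducer_reactions(p: KineticParams, galactose: float) -> list[Reaction]:
    """Galactose activation of Gal3/Gal1 and 1-to-1 Gal80 sequestration.

    Internal galactose is galactose * (c0 + c2 * Gal2/(Gal2 + K2)) with
    Gal2 read as a concentration; the import factor is encoded as the
    activation reaction's regulator Hill with basal c0/(c0+c2).
    """
    k_full = p.k_gact * galactose * (p.import_c0 + p.import_c2)
    import_basal = p.import_c0 / (p.import_c0 + p.import_c2)
    out = []
    for g, ga, w in (("Gal3", "Gal3a", 1.0), ("Gal1", "Gal1a", p.w1)):
        out += [
            Reaction(f"{g}:activate", "uni", k_full * w, s1=g,
                     reg="Gal2", reg_K=p.K2, reg_n=1.0,
                     reg_basal=import_basal, stoich={g: -1, ga: 1},
                     extrinsic=True),
            Reaction(f"{ga}:deactivate", "uni", p.k_gdeact, s1=ga,
                     stoich={ga: -1, g: 1}),
        ]
    for ga, c in (("Gal3a", "C3"), ("Gal1a", "C1")):
        out += [
            Reaction(f"{ga}:seq", "bi", p.k_seq, s1=ga, s2="Gal80", vexp=-1.0,
                     stoich={ga: -1, "Gal80": -1, c: 1}),
            Reaction(f"{c}:unseq", "uni", p.k_unseq, s1=c,
                     stoich={c: -1, ga: 1, "Gal80": 1}),
        ]
    return out


def _gal_core(p: KineticParams, galactose: float, copies: int,
              reporter_copies: int, gal80_reactions: list[Reaction],
              extra_species: list[str], extra_loci: list[GeneLocus],
              init_overrides: dict[str, int]) -> ReactionNetwork:
    species = ["Gal4", "Gal3", "Gal3a", "Gal1", "Gal1a", "Gal2", "Gal80",
               "C3", "C1", "YFP"] + extra_species
    loci = [
        GeneLocus("P_GAL4", copies=copies, init_on=copies),
        GeneLocus("P_GAL3", copies=copies),
        GeneLocus("P_GAL1", copies=copies),
        GeneLocus("P_GAL2", copies=copies),
        *extra_loci,
        GeneLocus("P_GAL1_YFP", copies=reporter_copies),
    ]
    reactions: list[Reaction] = [
        # Gal4 is constitutive: synthesis per total copy of an always-ON locus
        Reaction("P_GAL4:syn", "per_tot", p.ks_gal4, locus="P_GAL4",
                 stoich={"Gal4": 1}),
    ]
    for locus, product, rate in (("P_GAL3", "Gal3", p.ks_gal3),
                                 ("P_GAL1", "Gal1", p.ks_gal1),
                                 ("P_GAL2", "Gal2", p.ks_gal2),
                                 ("P_GAL1_YFP", "YFP", p.ks_yfp)):
        reactions += _regulated_locus_reactions(p, locus)
        reactions += _expression_reactions(p, locus, product, rate)
    reactions += gal80_reactions
    reactions += _inducer_reactions(p, galactose)
    reactions += _decay(p, ["Gal4", "Gal3", "Gal3a", "Gal1", "Gal1a", "Gal2",
                            "Gal80", "C3", "C1"])
    reactions.append(Reaction("YFP:decay", "uni", p.delta_yfp, s1="YFP",
                              stoich={"YFP": -1}))
    # uninduced-state initial counts (rough OFF-state means per network copy)
    init = {"Gal4": 35 * copies, "Gal3": 4 * copies, "Gal1": 4 * copies,
            "Gal2": 3 * copies, "Gal80": 15 * copies}
    init.update(init_overrides)
    return ReactionNetwork(species, loci, reactions, init)


def build_natural(params: KineticParams, galactose: float,
                  ploidy: int = 1, copies: int = 1) -> ReactionNetwork:
    """Natural GAL topology: Gal80 from its own Gal4-regulated promoter.

    ``copies`` is the network dosage (copy count of every regulatory gene
    locus); ``ploidy`` sets the reporter copy count and is expected to be
    paired with a cell-cycle model whose birth volume scales the same way
    (see :func:`default_cell_cycle` and ``cellsim.apply_ploidy``).
    """
    _check_gal_args(galactose, ploidy, copies)
    p = params
    gal80_rx = (_regulated_locus_reactions(p, "P_GAL80")
                + _expression_reactions(p, "P_GAL80", "Gal80", p.ks_gal80,
                                        p.gal80_basal_frac))
    return _gal_core(p, galactose, copies, reporter_copies=ploidy,
                     gal80_reactions=gal80_rx, extra_species=[],
                     extra_loci=[GeneLocus("P_GAL80", copies=copies)],
                     init_overrides={})


def build_synthetic(params: KineticParams, galactose: float,
                    dox: float | None = None,
                    ploidy: int = 1, copies: int = 1) -> ReactionNetwork:
    """Synthetic GAL topology: gal80-deleted background carrying
    P_GAL80-rtTA and P_TET-GAL80.

    rtTA is expressed from the Gal80 promoter (keeping the negative
    feedback loop intact) and drives Gal80 from the TET promoter, whose
    ON-switching rate is a Hill function (coefficient 2, one per rtTA
    operator) of rtTA * doxycycline.
    """
    _check_gal_args(galactose, ploidy, copies)
    p = params
    dox = p.dox if dox is None else dox
    if dox < 0:
        raise ValueError("dox must be nonnegative")
    rx = (_regulated_locus_reactions(p, "P_GAL80_rtTA")
          + _expression_reactions(p, "P_GAL80_rtTA", "rtTA", p.ks_rtta,
                                  p.gal80_basal_frac))
    rx += _tet_switch(p, "P_TET_GAL80", dox)
    rx += [
        Reaction("P_TET_GAL80:syn", "per_on", p.ks_gal80_tet,
                 locus="P_TET_GAL80", stoich={"Gal80": 1}),
        Reaction("rtTA:decay", "uni", p.delta_p, s1="rtTA",
                 stoich={"rtTA": -1}),
    ]
    return _gal_core(p, galactose, copies, reporter_copies=ploidy,
                     gal80_reactions=rx, extra_species=["rtTA"],
                     extra_loci=[GeneLocus("P_GAL80_rtTA", copies=copies),
                                 GeneLocus("P_TET_GAL80", copies=copies)],
                     init_overrides={"rtTA": 15 * copies})


def _check_gal_args(galactose: float, ploidy: int, copies: int) -> None:
    if galactose < 0:
        raise ValueError("galactose must be nonnegative")
    if copies < 1 or ploidy not in (1, 2):
        raise ValueError("copies must be >= 1 and ploidy in {1, 2}")


def _tet_switch(p: KineticParams, locus: str, dox: float) -> list[Reaction]:
    """TET-promoter ON/OFF switching driven by rtTA * dox (Hill 2)."""
    out = []
    if dox > 0:
        out.append(Reaction(f"{locus}:on", "per_off", p.k_on_tet,
                            locus=locus, dlocus=+1,
                            reg="rtTA", reg_K=p.K_tet / dox, reg_n=p.n_tet,
                            reg_basal=p.tet_basal_frac))
    elif p.tet_basal_frac > 0:
        out.append(Reaction(f"{locus}:on", "per_off",
                            p.k_on_tet * p.tet_basal_frac,
                            locus=locus, dlocus=+1))
    out.append(Reaction(f"{locus}:off", "per_on", p.k_off_tet,
                        locus=locus, dlocus=-1))
    return out


def build_cascade(params: KineticParams, beta_estradiol: float,
                  with_tet_link: bool = False,
                  dox: float | None = None) -> ReactionNetwork:
    """Monostable beta-estradiol cascade, orthogonal to the GAL network.

    A constitutive LexA-ER-AD fusion is activated by beta-estradiol (nM);
    without the link, P_LexA drives YFP directly; with the link, P_LexA
    drives rtTA and YFP is expressed from P_TET (rtTA * dox, Hill 2).
    """
    if beta_estradiol < 0:
        raise ValueError("beta_estradiol must be nonnegative")
    p = params
    dox = p.dox_cascade if dox is None else dox
    if dox < 0:
        raise ValueError("dox must be nonnegative")
    e = beta_estradiol
    species = ["LexA", "YFP"]
    loci = [GeneLocus("P_ACT1_LexA", copies=1, init_on=1),
            GeneLocus("P_LexA", copies=1)]
    rx = [
        Reaction("P_ACT1_LexA:syn", "per_tot", p.ks_lexa, locus="P_ACT1_LexA",
                 stoich={"LexA": 1}),
        Reaction("LexA:decay", "uni", p.delta_p, s1="LexA",
                 stoich={"LexA": -1}),
        Reaction("YFP:decay", "uni", p.delta_yfp, s1="YFP",
                 stoich={"YFP": -1}),
    ]
    if e > 0:
        # active LexA fraction e/(e+Ke) folded into the Hill K of P_LexA
        lexa_K = p.K_lexa * (p.K_estradiol + e) / e
        rx.append(Reaction("P_LexA:on", "per_off", p.k_on_lexa,
                           locus="P_LexA", dlocus=+1, reg="LexA",
                           reg_K=lexa_K, reg_n=p.n_lexa, reg_basal=0.0))
    else:
        # zero-estradiol limit: no activation (rate 0, same structure)
        rx.append(Reaction("P_LexA:on", "per_off", 0.0, locus="P_LexA",
                           dlocus=+1))
    rx.append(Reaction("P_LexA:off", "per_on", p.k_off_lexa, locus="P_LexA",
                       dlocus=-1))
    if not with_tet_link:
        rx.append(Reaction("P_LexA:syn", "per_on", p.ks_yfp_cascade,
                           locus="P_LexA", stoich={"YFP": 1}))
    else:
        species.append("rtTA")
        loci.append(GeneLocus("P_TET", copies=1))
        # rtTA replaces YFP as the P_LexA output (full promoter strength);
        # the P_TET-YFP construct switches with the cascade promoter class
        # kinetics, its ON rate a Hill function (coefficient 2) of rtTA*dox
        rx += [
            Reaction("P_LexA:syn", "per_on", p.ks_yfp_cascade, locus="P_LexA",
                     stoich={"rtTA": 1}),
            Reaction("rtTA:decay", "uni", p.delta_p, s1="rtTA",
                     stoich={"rtTA": -1}),
            Reaction("P_TET:syn", "per_on", p.ks_yfp_cascade, locus="P_TET",
                     stoich={"YFP": 1}),
        ]
        if dox > 0:
            rx.append(Reaction("P_TET:on", "per_off", p.k_on_lexa,
                               locus="P_TET", dlocus=+1,
                               reg="rtTA", reg_K=p.K_tet / dox,
                               reg_n=p.n_tet, reg_basal=p.tet_basal_frac))
        else:
            rx.append(Reaction("P_TET:on", "per_off",
                               p.k_on_lexa * p.tet_basal_frac,
                               locus="P_TET", dlocus=+1))
        rx.append(Reaction("P_TET:off", "per_on", p.k_off_lexa,
                           locus="P_TET", dlocus=-1))
    return ReactionNetwork(species, loci, rx, {"LexA": 35})


def _reaction_signature(r: Reaction):
    return (r.name, r.base, round(r.k, 12), r.s1, r.s2, r.locus, r.vexp,
            r.reg, round(r.reg_K, 12), r.reg_n, round(r.reg_basal, 12),
            tuple(sorted(r.stoich.items())), r.dlocus)


def structural_diff(a: ReactionNetwork, b: ReactionNetwork) -> dict:
    """Structural difference between two networks.

    Returns species, loci and reactions present in one network but not the
    other (reactions by full signature including rate constants).  Used to
    audit that the natural and synthetic topologies differ only in the
    Gal80-production subgraph.
    """
    sa = {_reaction_signature(r) for r in a.reactions}
    sb = {_reaction_signature(r) for r in b.reactions}
    la = {(l.name, l.copies) for l in a.loci}
    lb = {(l.name, l.copies) for l in b.loci}
    return {
        "species_only_a": sorted(set(a.species) - set(b.species)),
        "species_only_b": sorted(set(b.species) - set(a.species)),
        "loci_only_a": sorted(la - lb),
        "loci_only_b": sorted(lb - la),
        "reactions_only_a": sorted(r[0] for r in sa - sb),
        "reactions_only_b": sorted(r[0] for r in sb - sa),
    }
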