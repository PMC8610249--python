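"""Parameterization of the reduced thin-film clotting model.

The model describes coagulation triggered by tissue factor (TF) under
venous flow in a thin (15 um) porous platelet/fibrin layer.  Because the
layer is thin, zymogen substrates (FX, FIX, FII, FXI, fibrinogen) are
replenished by diffusion from flowing blood and stay clamped at their
plasma levels, so every catalytic step reduces to a first-order reaction
in its enzyme with rate

    alpha = kcat * S0 / (Km + S0)

scaled by an effectiveness factor ``eta`` that absorbs residual transport
limits.  Seven such reactions (extrinsic tenase activating FX and FIX,
intrinsic tenase, prothrombinase, fibrin generation, thrombin-mediated FXI
activation on platelets, and FXIa-mediated FIX activation) plus two
reversible thrombin-to-fibrin binding equilibria define the network.

This module holds the domain types (:class:`ReactionSpec`,
:class:`BindingSiteSpec`, :class:`ModelConfig`, :class:`VariantVector`),
the packaged default parameter table, and :func:`build_parameters`, which
turns specs + configuration + a variant multiplier vector into the flat
:class:`RateSet` consumed by the integrator.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "AVOGADRO",
    "LN2",
    "VARIABLES",
    "ParameterError",
    "ReactionSpec",
    "BindingSiteSpec",
    "ParameterSet",
    "ModelConfig",
    "VariantVector",
    "RateSet",
    "compute_alpha",
    "surface_to_volume_concentration",
    "build_parameters",
    "load_parameters",
    "save_parameters",
    "alpha_discrepancy_report",
]

AVOGADRO = 6.02214076e23
LN2 = math.log(2.0)

#: Canonical order of the 7 varied inputs (5 plasma zymogens, 2 thrombin
#: binding-site densities).  Every sample matrix, variant vector and report
#: uses this column order.
VARIABLES = (
    "FXI",
    "FIX",
    "FX",
    "FII",
    "fibrinogen",
    "weak_E_sites",
    "gamma_prime_sites",
)

_ZYMOGENS = ("FXI", "FIX", "FX", "FII", "fibrinogen")
_SITE_IDS = ("weak_E", "gamma_prime")
_ENZYME_SPECIES = ("IXa", "Xa", "XIa", "IIa")


class ParameterError(ValueError):
    """Invalid model parameter or variant multiplier."""


def compute_alpha(kcat: float, Km: float, S0: float) -> float:
    """First-order rate of a substrate-clamped Michaelis-Menten reaction.

    With the substrate held at its plasma level ``S0``, the turnover per
    unit enzyme is ``kcat * S0 / (Km + S0)`` (1/s).  Monotone
    non-decreasing in ``S0`` and bounded above by ``kcat``.
    """
    if Km <= 0:
        raise ParameterError(f"Km must be positive, got {Km}")
    if S0 < 0:
        raise ParameterError(f"S0 must be non-negative, got {S0}")
    return kcat * S0 / (Km + S0)


def surface_to_volume_concentration(
    sigma: float, delta: float, porosity: float
) -> float:
    """Convert a surface density to a volumetric concentration in nM.

    A species presented at ``sigma`` molecules/um^2 on the wall, dispersed
    through a film of thickness ``delta`` um with the given porosity,
    corresponds to ``sigma / (delta * porosity)`` molecules/um^3.
    """
    if delta <= 0:
        raise ParameterError(f"film thickness must be positive, got {delta}")
    if not 0 < porosity <= 1:
        raise ParameterError(f"porosity must be in (0, 1], got {porosity}")
    per_um3 = sigma / (delta * porosity)
    # molecules/um^3 -> mol/L -> nM:  1 um^3 = 1e-15 L
    return per_um3 * 1e15 / AVOGADRO * 1e9


@dataclass(frozen=True)
class ReactionSpec:
    """One linearized catalytic reaction of the cascade.

    ``alpha_printed`` is the published first-order rate for this reaction;
    it is retained for regression reporting (see
    :func:`alpha_discrepancy_report`) and for the ``use_printed_alpha``
    configuration switch, but by default rates are recomputed from
    ``kcat``, ``Km`` and ``S0``.
    """

    id: int
    enzyme: str
    product: str
    substrate: str
    S0: float
    kcat: float
    Km: float
    eta: float
    alpha_printed: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.id <= 7:
            raise ParameterError(f"reaction id must be 1..7, got {self.id}")
        if self.kcat <= 0:
            raise ParameterError(f"reaction {self.id}: kcat must be > 0")
        if self.Km <= 0:
            raise ParameterError(f"reaction {self.id}: Km must be > 0")
        if self.S0 < 0:
            raise ParameterError(f"reaction {self.id}: S0 must be >= 0")
        if not 0 < self.eta <= 1:
            raise ParameterError(f"reaction {self.id}: eta must be in (0, 1]")
        if self.substrate not in _ZYMOGENS:
            raise ParameterError(
                f"reaction {self.id}: unknown substrate {self.substrate!r}"
            )

    def alpha(self, multiplier: float = 1.0, use_printed: bool = False) -> float:
        """Effective first-order rate with the substrate scaled by ``multiplier``.

        When ``use_printed`` is set and a printed rate is available, the
        printed value is used at baseline and rescaled by the formula ratio
        away from baseline, so the variant-scaling behaviour is preserved.
        """
        a = compute_alpha(self.kcat, self.Km, self.S0 * multiplier)
        if use_printed and self.alpha_printed is not None:
            base = compute_alpha(self.kcat, self.Km, self.S0)
            return self.alpha_printed * (a / base if base > 0 else 0.0)
        return a


@dataclass(frozen=True)
class BindingSiteSpec:
    """A reversible thrombin binding site carried by fibrin.

    ``sites_per_fibrin`` is the effective number of sites generated per uM
    of fibrin monomer formed; the total site concentration at any instant
    is ``sites_per_fibrin * [fibrin]``.
    """

    site_id: str
    kf: float  # 1/(uM s)
    kr: float  # 1/s
    sites_per_fibrin: float

    def __post_init__(self) -> None:
        if self.site_id not in _SITE_IDS:
            raise ParameterError(f"unknown binding site {self.site_id!r}")
        if self.kf <= 0 or self.kr <= 0:
            raise ParameterError(f"site {self.site_id}: kf and kr must be > 0")
        if self.sites_per_fibrin <= 0:
            raise ParameterError(
                f"site {self.site_id}: sites_per_fibrin must be > 0"
            )

    @property
    def Kd(self) -> float:
        """Dissociation constant kr/kf in uM."""
        return self.kr / self.kf


@dataclass(frozen=True)
class ParameterSet:
    """The seven reactions and two binding sites of the model."""

    reactions: tuple[ReactionSpec, ...]
    sites: tuple[BindingSiteSpec, ...]

    def __post_init__(self) -> None:
        ids = sorted(r.id for r in self.reactions)
        if ids != list(range(1, 8)):
            raise ParameterError(f"need reactions 1..7 exactly once, got ids {ids}")
        site_ids = sorted(s.site_id for s in self.sites)
        if site_ids != sorted(_SITE_IDS):
            raise ParameterError(f"need sites {_SITE_IDS}, got {site_ids}")
        object.__setattr__(
            self, "reactions", tuple(sorted(self.reactions, key=lambda r: r.id))
        )

    def reaction(self, rid: int) -> ReactionSpec:
        return self.reactions[rid - 1]

    def site(self, site_id: str) -> BindingSiteSpec:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise ParameterError(f"unknown binding site {site_id!r}")

    def with_stoichiometry(self, weak_E: float, gamma_prime: float) -> "ParameterSet":
        """Return a copy with replaced sites-per-fibrin stoichiometries."""
        new_sites = tuple(
            dataclasses.replace(
                s,
                sites_per_fibrin=weak_E if s.site_id == "weak_E" else gamma_prime,
            )
            for s in self.sites
        )
        return dataclasses.replace(self, sites=new_sites)

    def to_dict(self) -> dict:
        return {
            "reactions": [dataclasses.asdict(r) for r in self.reactions],
            "binding_sites": [dataclasses.asdict(s) for s in self.sites],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        try:
            reactions = tuple(ReactionSpec(**r) for r in d["reactions"])
            sites = tuple(BindingSiteSpec(**s) for s in d["binding_sites"])
        except (KeyError, TypeError) as exc:
            raise ParameterError(f"malformed parameter file: {exc}") from exc
        return cls(reactions=reactions, sites=sites)


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a parameter file (YAML); ``None`` loads the packaged defaults."""
    if path is None:
        text = (
            resources.files("clotfilm.data")
            .joinpath("default_parameters.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    return ParameterSet.from_dict(yaml.safe_load(text))


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class ModelConfig:
    """Geometry, half-lives, horizon, solver settings and model switches.

    Half-lives: every free active protease is inactivated by plasma
    inhibitors with a 1-minute half-life; active tissue factor decays with
    a 3-minute half-life; soluble species additionally wash out of the film
    with a 2-second elution half-life.  Elution applies to the species in
    ``eluting_species`` (default: FXa and free thrombin).  FIXa and FXIa
    act within platelet-membrane complexes (intrinsic tenase, platelet-
    bound FXIa) and are retained; fibrin-bound thrombin is protected from
    both inactivation and elution.

    ``tf_active_fraction`` is the fraction of wall TF present as active
    TF:VIIa complex; the absolute active-TF level is not published and the
    shipped default is calibrated (see docs/methods.md).
    """

    delta: float = 15.0  # film thickness, um
    porosity: float = 0.5
    tf_surface_density: float = 1.0  # TF molecules per um^2
    tf_active_fraction: float = 0.07
    t_half_enzyme: float = 60.0  # s
    t_half_tf: float = 180.0  # s
    t_half_elution: float = 2.0  # s
    tat_fraction: float = 0.7
    t_end: float = 800.0  # s
    output_dt: float = 1.0  # s
    rtol: float = 1e-8
    atol: float = 1e-12  # uM
    fxi_knockout: bool = False
    gprp_mode: bool = False
    use_printed_alpha: bool = False
    tat_includes_inactivation: bool = True
    eluting_species: tuple[str, ...] = ("Xa", "IIa")

    def __post_init__(self) -> None:
        for name in ("t_half_enzyme", "t_half_tf", "t_half_elution", "t_end"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 <= self.tat_fraction <= 1:
            raise ParameterError("tat_fraction must be in [0, 1]")
        if not 0 < self.porosity <= 1:
            raise ParameterError("porosity must be in (0, 1]")
        if self.delta <= 0:
            raise ParameterError("delta must be positive")
        if not 0 < self.tf_active_fraction <= 1:
            raise ParameterError("tf_active_fraction must be in (0, 1]")
        if self.output_dt <= 0:
            raise ParameterError("output_dt must be positive")
        unknown = set(self.eluting_species) - set(_ENZYME_SPECIES)
        if unknown:
            raise ParameterError(f"unknown eluting species {sorted(unknown)}")

    def replace(self, **changes) -> "ModelConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class VariantVector:
    """Multipliers applied to the 7 varied inputs, each in [0.5, 1.5].

    The all-ones vector reproduces baseline parameters exactly.  Knockouts
    are configuration flags, not multipliers, so the range contract stays
    tight for Monte Carlo sampling.
    """

    FXI: float = 1.0
    FIX: float = 1.0
    FX: float = 1.0
    FII: float = 1.0
    fibrinogen: float = 1.0
    weak_E_sites: float = 1.0
    gamma_prime_sites: float = 1.0

    LOW = 0.5
    HIGH = 1.5

    def __post_init__(self) -> None:
        for name in VARIABLES:
            v = getattr(self, name)
            if not self.LOW <= v <= self.HIGH:
                raise ParameterError(
                    f"multiplier {name}={v} outside [{self.LOW}, {self.HIGH}]"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in VARIABLES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "VariantVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(VARIABLES),):
            raise ParameterError(
                f"expected {len(VARIABLES)} multipliers, got shape {values.shape}"
            )
        return cls(**dict(zip(VARIABLES, values)))

    @classmethod
    def from_mapping(cls, mapping) -> "VariantVector":
        unknown = set(mapping) - set(VARIABLES)
        if unknown:
            raise ParameterError(f"unknown variables {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def baseline(cls) -> "VariantVector":
        return cls()


@dataclass(frozen=True)
class RateSet:
    """Flat, variant-resolved rate constants consumed by the integrator.

    ``r`` holds the seven effective first-order rates ``eta_i * alpha_i``
    (1/s); decay constants are per-species totals (inactivation plus
    elution where applicable); ``sw``/``sg`` are site densities per uM
    fibrin; ``TF0`` is the initial active TF:VIIa concentration in uM.
    """

    r: tuple[float, ...]  # r1..r7, 1/s
    kTF: float
    kIXa: float
    kXa: float
    kXIa: float
    kIIa: float
    kin: float  # inactivation component, 1/s
    kel_IIa: float  # elution component of thrombin decay, 1/s
    kfw: float
    krw: float
    sw: float
    kfg: float
    krg: float
    sg: float
    TF0: float  # uM

    def packed(self) -> np.ndarray:
        """Parameter vector in the layout expected by the ODE right-hand side."""
        return np.array(
            [
                *self.r,
                self.kTF,
                self.kIXa,
                self.kXa,
                self.kXIa,
                self.kIIa,
                self.kin,
                self.kel_IIa,
                self.kfw,
                self.krw,
                self.sw,
                self.kfg,
                self.krg,
                self.sg,
            ]
        )


def build_parameters(
    params: ParameterSet,
    config: ModelConfig,
    variant: VariantVector | None = None,
) -> RateSet:
    """Resolve specs + configuration + variant multipliers into a RateSet.

    Substrate multipliers rescale the alpha of every reaction consuming
    that zymogen (the FIX multiplier rescales reactions 2 and 7, the FX
    multiplier reactions 1 and 3); site multipliers rescale the
    sites-per-fibrin stoichiometries.  The FXIa-knockout flag zeroes the
    feedback rates r6 and r7; GPRP mode disables binding-site generation.
    """
    if variant is None:
        variant = VariantVector.baseline()
    elif not isinstance(variant, VariantVector):
        variant = (
            VariantVector.from_mapping(variant)
            if isinstance(variant, dict)
            else VariantVector.from_array(variant)
        )

    r = []
    for spec in params.reactions:
        mult = getattr(variant, spec.substrate)
        r.append(spec.eta * spec.alpha(mult, use_printed=config.use_printed_alpha))
    if config.fxi_knockout:
        r[5] = 0.0  # reaction 6: IIa-mediated FXI activation
        r[6] = 0.0  # reaction 7: FXIa-mediated FIX activation

    weak = params.site("weak_E")
    gamma = params.site("gamma_prime")
    sw = weak.sites_per_fibrin * variant.weak_E_sites
    sg = gamma.sites_per_fibrin * variant.gamma_prime_sites
    if config.gprp_mode:
        sw = sg = 0.0

    kin = LN2 / config.t_half_enzyme
    kel = LN2 / config.t_half_elution
    decay = {
        sp: kin + (kel if sp in config.eluting_species else 0.0)
        for sp in _ENZYME_SPECIES
    }

    tf0_nM = (
        surface_to_volume_concentration(
            config.tf_surface_density, config.delta, config.porosity
        )
        * config.tf_active_fraction
    )

    return RateSet(
        r=tuple(r),
        kTF=LN2 / config.t_half_tf,
        kIXa=decay["IXa"],
        kXa=decay["Xa"],
        kXIa=decay["XIa"],
        kIIa=decay["IIa"],
        kin=kin,
        kel_IIa=decay["IIa"] - kin,
        kfw=weak.kf,
        krw=weak.kr,
        sw=sw,
        kfg=gamma.kf,
        krg=gamma.kr,
        sg=sg,
        TF0=tf0_nM * 1e-3,
    )


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def alpha_discrepancy_report(params: ParameterSet):
    """Compare recomputed first-order rates with the published values.

    Returns a DataFrame with one row per reaction: the rate recomputed
    from kcat, Km and S0, the published rate, their ratio, and whether
    they agree to two significant figures.  Reactions 1, 3 and 5 are known
    not to agree (reaction 5 by roughly an order of magnitude); the model
    uses the recomputed values by default and exposes the published column
    behind the ``use_printed_alpha`` switch rather than silently patching
    either side.
    """
    import pandas as pd

    rows = []
    for spec in params.reactions:
        a = compute_alpha(spec.kcat, spec.Km, spec.S0)
        printed = spec.alpha_printed
        rows.append(
            {
                "reaction": spec.id,
                "alpha_formula": a,
                "alpha_printed": printed,
                "ratio": a / printed if printed else np.nan,
                "matches_2sf": (
                    printed is not None
                    and _round_sig(a, 2) == _round_sig(printed, 2)
                ),
            }
        )
    return pd.DataFrame(rows).set_index("reaction")
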