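"""Chemical-specific parameters: partitioning, absorption/elimination,
and saturable gut/liver metabolism of DEHP and MEHP.

DEHP (di(2-ethylhexyl) phthalate) is hydrolysed to MEHP (mono(2-ethylhexyl)
phthalate) by microsomal and cytosolic lipases in the gut and the liver;
MEHP is further oxidised to downstream metabolites (5-OH MEHP, 5-cx MEPP,
5-oxo MEHP, phthalic acid) which this model pools into a single loss sink.
Michaelis-Menten capacities are tabulated per mg of microsomal (MSP) or
cytosolic protein and scaled to whole-organ capacity with protein-content
constants via :func:`scale_metabolic_capacity`.

Uncertain parameters carry lognormal uncertainty specifications (median
and geometric SD factor, draws truncated at +/-1.5 geometric SDs) for
Monte Carlo propagation; default simulations use the medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

__all__ = [
    "SpeciesParams",
    "MetabolicReaction",
    "KineticConstants",
    "LognormalSpec",
    "ChemistrySet",
    "default_chemistry",
    "scale_metabolic_capacity",
    "sample_parameters",
    "MW_DEHP",
    "MW_MEHP",
    "MW_MEHP_D4",
    "DEFAULT_PROTEIN_MG_PER_G",
]

MW_DEHP = 391.0
#: Non-deuterated MEHP, used for the exposure scenarios.
MW_MEHP = 278.3
#: Deuterium-labelled (D4) MEHP, used for the labelled single-dose run.
MW_MEHP_D4 = 281.0

#: Protein content of the metabolizing tissues, mg protein per g tissue.
#: Keys are (organ, pool) with pool "msp" (microsomal) or "cyt" (cytosolic).
DEFAULT_PROTEIN_MG_PER_G: dict[tuple[str, str], float] = {
    ("liver", "msp"): 40.0,
    ("liver", "cyt"): 80.7,
    ("gut", "msp"): 3.0,
    ("gut", "cyt"): 3.0,
}

#: Truncation of lognormal draws, in geometric standard deviations.
TRUNCATION_SD = 1.5


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal uncertainty: median and geometric SD factor."""

    median: float
    sd_factor: float

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("lognormal median must be > 0")
        if self.sd_factor < 1:
            raise ValueError("lognormal sd_factor must be >= 1")


@dataclass
class SpeciesParams:
    """Per-species physicochemical parameters.

    ``partition`` maps organ name to the tissue:plasma partition
    coefficient Kp.  Organs without a measured Kp use the rest-of-body
    value; fat Kp is carried for completeness but the body has no
    adipose compartment, so it is unused by default.
    """

    name: str
    molecular_weight: float
    partition: dict[str, float]
    log_kow: float | None = None
    fup: float | None = None

    def __post_init__(self) -> None:
        if any(kp <= 0 for kp in self.partition.values()):
            raise ValueError(f"{self.name}: all Kp must be > 0")
        if self.fup is not None and not (0 < self.fup <= 1):
            raise ValueError(f"{self.name}: fup must be in (0, 1]")

    def kp(self, organ: str) -> float:
        return self.partition.get(organ, self.partition["rest_of_body"])


@dataclass
class MetabolicReaction:
    """One saturable reaction: vmax in ug/min per mg protein, Km in ug/L.

    A reaction with vmax = km = 0 is disabled.  ``product`` is either
    "MEHP" (hydrolysis of DEHP) or "sink" (oxidation of MEHP to pooled
    downstream metabolites).
    """

    id: str
    organ: str
    pool: str  # "msp" | "cyt"
    vmax_ug_per_min_per_mg: float
    km_ug_per_l: float
    substrate: str
    product: str

    def __post_init__(self) -> None:
        if self.vmax_ug_per_min_per_mg < 0 or self.km_ug_per_l < 0:
            raise ValueError(f"{self.id}: vmax and km must be >= 0")
        if self.km_ug_per_l == 0 and self.vmax_ug_per_min_per_mg > 0:
            raise ValueError(f"{self.id}: km = 0 requires vmax = 0 (disabled reaction)")

    @property
    def enabled(self) -> bool:
        return self.vmax_ug_per_min_per_mg > 0


@dataclass
class KineticConstants:
    """First-order absorption and elimination constants (1/h)."""

    kgut: float = 7.0
    kurine: float = 0.35

    def __post_init__(self) -> None:
        if self.kgut <= 0 or self.kurine < 0:
            raise ValueError("kgut must be > 0 and kurine >= 0")


@dataclass
class ChemistrySet:
    """The full chemical parameter set for a simulation."""

    species: dict[str, SpeciesParams]
    reactions: list[MetabolicReaction]
    kinetics: KineticConstants
    fup_mehp: float = 0.007
    lognormal: dict[str, LognormalSpec] = field(default_factory=dict)
    #: Blood-uptake rates of downstream metabolites (1/h); loaded for
    #: completeness but inert while those metabolites are sink-pooled.
    auxiliary: dict[str, float] = field(default_factory=dict)

    def reaction(self, rid: str) -> MetabolicReaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def to_dict(self) -> dict:
        return {
            "species": {k: asdict(v) for k, v in self.species.items()},
            "reactions": [asdict(r) for r in self.reactions],
            "kinetics": asdict(self.kinetics),
            "fup_mehp": self.fup_mehp,
            "lognormal": {k: asdict(v) for k, v in self.lognormal.items()},
            "auxiliary": dict(self.auxiliary),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChemistrySet":
        return cls(
            species={k: SpeciesParams(**v) for k, v in d["species"].items()},
            reactions=[MetabolicReaction(**r) for r in d["reactions"]],
            kinetics=KineticConstants(**d["kinetics"]),
            fup_mehp=d["fup_mehp"],
            lognormal={k: LognormalSpec(**v) for k, v in d["lognormal"].items()},
            auxiliary=dict(d["auxiliary"]),
        )


def _reactions_table() -> list[MetabolicReaction]:
    R = MetabolicReaction
    return [
        R("gut_msp_M1", "gut", "msp", 0.11, 6956.0, "DEHP", "MEHP"),
        R("gut_cyt_M1", "gut", "cyt", 0.312, 7038.0, "DEHP", "MEHP"),
        R("gut_M2", "gut", "msp", 0.0012, 22508.0, "MEHP", "sink"),
        R("gut_M3", "gut", "msp", 0.0, 0.0, "MEHP", "sink"),  # disabled
        R("gut_M4", "gut", "msp", 0.0012, 219076.0, "MEHP", "sink"),
        # Printed as mg/min/mg in the source table; read on the ug basis
        # like every other capacity (unit typo), see default_chemistry().
        R("gut_M5", "gut", "msp", 0.285, 187652.0, "MEHP", "sink"),
        # Liver microsomal M1 Km is not tabulated; the intestinal
        # microsomal value for the same hydrolysis reaction is used.
        R("liver_msp_M1", "liver", "msp", 0.112, 6956.0, "DEHP", "MEHP"),
        R("liver_cyt_M1", "liver", "cyt", 0.036, 2228.7, "DEHP", "MEHP"),
        R("liver_M2", "liver", "msp", 0.172, 7980.4, "MEHP", "sink"),
        R("liver_M3", "liver", "msp", 0.0023, 1124.0, "MEHP", "sink"),
        R("liver_M4", "liver", "msp", 0.003, 23117.7, "MEHP", "sink"),
        R("liver_M5", "liver", "msp", 0.088, 141315.0, "MEHP", "sink"),
    ]


# Geometric SD factors attached to uncertain parameters.
_LOGNORMAL_SPECS: dict[str, tuple[float, float]] = {
    "kp_dehp_gut": (12.86, 1.1),
    "kp_dehp_liver": (10.16, 1.1),
    "kp_dehp_fat": (188.0, 1.1),
    "kp_dehp_rest": (6.24, 1.1),
    "kp_mehp_liver": (1.7, 1.1),
    "kp_mehp_fat": (0.12, 1.1),
    "kp_mehp_rest": (0.38, 1.1),
    "kgut": (7.0, 1.5),
    "kurine": (0.35, 1.1),
    "kt_m2": (0.07, 1.5),
    "kt_m4": (0.08, 1.5),
    "vmax_gut_msp_M1": (0.11, 1.1),
    "vmax_gut_cyt_M1": (0.312, 1.1),
    "vmax_gut_M2": (0.0012, 1.1),
    "vmax_gut_M4": (0.0012, 1.5),
    "vmax_gut_M5": (0.285, 1.1),
    "vmax_liver_msp_M1": (0.112, 1.1),
    "vmax_liver_cyt_M1": (0.036, 1.1),
    "vmax_liver_M2": (0.172, 1.1),
    "vmax_liver_M3": (0.0023, 1.5),
    "vmax_liver_M4": (0.003, 1.1),
    "vmax_liver_M5": (0.088, 1.1),
}


def default_chemistry(*, deuterated_mehp: bool = False) -> ChemistrySet:
    """The default DEHP/MEHP parameter set (medians of the uncertainty
    distributions).

    Parameters
    ----------
    deuterated_mehp
        Use the D4-labelled MEHP molecular weight (281 g/mol) instead of
        the non-deuterated 278.3 g/mol; the labelled weight is what the
        single-oral-dose validation experiment measured.
    """
    dehp = SpeciesParams(
        name="DEHP",
        molecular_weight=MW_DEHP,
        log_kow=7.6,
        partition={
            "gut": 12.86,
            "liver": 10.16,
            "fat": 188.0,
            "rest_of_body": 6.24,
        },
    )
    mehp = SpeciesParams(
        name="MEHP",
        molecular_weight=MW_MEHP_D4 if deuterated_mehp else MW_MEHP,
        fup=0.007,
        partition={
            "liver": 1.7,
            "fat": 0.12,
            "rest_of_body": 0.38,
        },
    )
    return ChemistrySet(
        species={"DEHP": dehp, "MEHP": mehp},
        reactions=_reactions_table(),
        kinetics=KineticConstants(kgut=7.0, kurine=0.35),
        fup_mehp=0.007,
        lognormal={k: LognormalSpec(*v) for k, v in _LOGNORMAL_SPECS.items()},
        auxiliary={"kt_m2": 0.07, "kt_m4": 0.08},
    )


def scale_metabolic_capacity(
    reactions: list[MetabolicReaction],
    physiology,
    protein_mg_per_g: dict[tuple[str, str], float] | None = None,
    tissue_density_g_per_ml: float = 1.0,
) -> dict[str, float]:
    """Scale per-mg-protein capacities to whole-organ Vmax in ug/h.

    Vmax_organ = vmax [ug/min/mg] * 60 [min/h] * protein [mg/g]
                 * tissue mass [g],  with mass = volume * density.
    """
    protein = DEFAULT_PROTEIN_MG_PER_G if protein_mg_per_g is None else protein_mg_per_g
    scaled: dict[str, float] = {}
    for r in reactions:
        if not r.enabled:
            scaled[r.id] = 0.0
            continue
        key = (r.organ, r.pool)
        if key not in protein:
            raise ValueError(
                f"no protein content configured for organ={r.organ!r} pool={r.pool!r}"
            )
        mass_g = physiology.volume(r.organ) * tissue_density_g_per_ml
        scaled[r.id] = r.vmax_ug_per_min_per_mg * 60.0 * protein[key] * mass_g
    return scaled


def sample_parameters(
    specs: dict[str, LognormalSpec],
    n: int,
    seed: int | np.random.Generator,
) -> "np.recarray":
    """Draw ``n`` joint parameter sets for Monte Carlo propagation.

    Each parameter is drawn independently from a lognormal with the
    given median and geometric SD, truncated to
    ``median * sd_factor**(+/-1.5)``; fixed seed gives identical draws.

    Returns a pandas-free structured array with one named column per
    parameter (all positive by construction).
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(specs)
    out = np.recarray((n,), dtype=[(name, float) for name in names])
    for name in names:
        s = specs[name]
        sigma = np.log(s.sd_factor)
        if sigma == 0.0:
            out[name] = s.median
            continue
        z = stats.truncnorm.rvs(
            -TRUNCATION_SD, TRUNCATION_SD, size=n, random_state=rng
        )
        out[name] = s.median * np.exp(sigma * z)
    return out
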