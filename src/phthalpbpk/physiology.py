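"""Anatomy and haemodynamics of the 16-compartment body.

The body is split into lungs, heart, brain, muscle, skin, liver, gut,
spleen, pancreas, bone, kidney, thymus, a lumped rest-of-body pool,
arterial and venous blood, and a cumulative urine accumulator.  Systemic
organs are perfused in parallel from arterial blood; the lungs sit in
series on total cardiac output between the venous and arterial pools.
Gut, spleen and pancreas drain through the portal vein into the liver,
which additionally receives a hepatic arterial supply.

Organ volumes follow a reference-human anatomy table; blood flows use a
bundled reference-human cardiac output and fractional organ flows, both
overridable through :func:`build_default_physiology`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "Compartment",
    "PhysiologyModel",
    "TopologyError",
    "TopologyReport",
    "build_default_physiology",
    "validate_topology",
    "DEFAULT_VOLUMES_ML",
    "DEFAULT_FLOW_FRACTIONS",
    "DEFAULT_CARDIAC_OUTPUT_ML_PER_H",
    "DEFAULT_BODY_WEIGHT_KG",
    "SYSTEMIC_ORGANS",
    "PORTAL_ORGANS",
]

#: Reference-human organ volumes (mL).
DEFAULT_VOLUMES_ML: dict[str, float] = {
    "arterial_blood": 1698.0,
    "bone": 4579.0,
    "brain": 1450.0,
    "gut": 1650.0,
    "heart": 310.0,
    "kidney": 280.0,
    "liver": 1690.0,
    "lungs": 1172.0,
    "muscle": 35000.0,
    "pancreas": 77.0,
    "rest_of_body": 49579.0,
    "skin": 7800.0,
    "spleen": 192.0,
    "thymus": 29.0,
    "urine": 1.0,
    "venous_blood": 3396.0,
}

#: Reference-human cardiac output: 5200 mL/min expressed per hour.
DEFAULT_CARDIAC_OUTPUT_ML_PER_H = 5200.0 * 60.0

#: Body weight used by the exposure scenarios (kg).
DEFAULT_BODY_WEIGHT_KG = 60.0

#: Fraction of cardiac output perfusing each systemic organ in parallel.
#: ``liver`` is the hepatic *arterial* fraction only; portal blood from
#: gut, spleen and pancreas reaches the liver on top of it.  Fractions
#: sum to 1 by construction (rest_of_body takes the remainder).
DEFAULT_FLOW_FRACTIONS: dict[str, float] = {
    "heart": 0.04,
    "brain": 0.12,
    "muscle": 0.17,
    "skin": 0.05,
    "gut": 0.15,
    "spleen": 0.03,
    "pancreas": 0.01,
    "bone": 0.05,
    "kidney": 0.19,
    "thymus": 0.0015,
    "liver": 0.065,
    "rest_of_body": 0.1235,
}

#: Systemic organs perfused in parallel from the arterial pool.
SYSTEMIC_ORGANS: tuple[str, ...] = tuple(DEFAULT_FLOW_FRACTIONS)

#: Organs whose venous outflow drains through the liver.
PORTAL_ORGANS: frozenset[str] = frozenset({"gut", "spleen", "pancreas"})

_METABOLIZING = frozenset({"gut", "liver"})
_BLOOD_POOLS = frozenset({"arterial_blood", "venous_blood"})


@dataclass(frozen=True)
class Compartment:
    """A single anatomical compartment.

    ``flow_fraction`` is the fraction of cardiac output perfusing the
    compartment in the parallel systemic circuit; it is 0 for the blood
    pools, the urine accumulator, and the lungs (which carry total
    cardiac output in series instead).
    """

    name: str
    volume_ml: float
    flow_fraction: float = 0.0
    is_metabolizing: bool = False

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError(f"compartment {self.name!r}: volume must be > 0")
        if self.flow_fraction < 0:
            raise ValueError(f"compartment {self.name!r}: negative flow fraction")


class TopologyError(ValueError):
    """Raised when the circulatory graph is malformed (e.g. an organ
    has no venous return path)."""


@dataclass
class PhysiologyModel:
    """The assembled body: compartments, cardiac output and plumbing.

    ``venous_links`` lists the systemic organs with an explicit return
    path (portal organs return via the liver).  ``liver_outflow_ml_per_h``
    is frozen at build time so that later edits to individual organ flows
    show up as flow-conservation residuals in :func:`validate_topology`.
    """

    compartments: dict[str, Compartment]
    cardiac_output_ml_per_h: float
    body_weight_kg: float
    portal_organs: frozenset[str] = PORTAL_ORGANS
    venous_links: set[str] = field(default_factory=lambda: set(SYSTEMIC_ORGANS))
    liver_outflow_ml_per_h: float = 0.0

    def volume(self, name: str) -> float:
        return self.compartments[name].volume_ml

    def organ_flow(self, name: str) -> float:
        """Parallel-circuit blood flow through a systemic organ (mL/h)."""
        return self.compartments[name].flow_fraction * self.cardiac_output_ml_per_h

    @property
    def systemic_organs(self) -> tuple[str, ...]:
        return tuple(
            c.name for c in self.compartments.values() if c.flow_fraction > 0
        )

    @property
    def liver_inflow_ml_per_h(self) -> float:
        """Hepatic artery plus portal drainage (mL/h)."""
        return self.organ_flow("liver") + sum(
            self.organ_flow(o) for o in self.portal_organs
        )

    def with_flow_fraction(self, organ: str, fraction: float) -> "PhysiologyModel":
        """Copy of the model with one organ's flow fraction replaced.

        Frozen bookkeeping quantities (liver outflow) are *not* updated,
        so the resulting imbalance is visible to :func:`validate_topology`.
        """
        comps = dict(self.compartments)
        comps[organ] = replace(comps[organ], flow_fraction=fraction)
        return replace(self, compartments=comps, venous_links=set(self.venous_links))


def build_default_physiology(
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG,
    *,
    cardiac_output_ml_per_h: float = DEFAULT_CARDIAC_OUTPUT_ML_PER_H,
    scale_volumes: bool = False,
    overrides: dict[str, dict[str, float]] | None = None,
) -> PhysiologyModel:
    """Build the reference 16-compartment body.

    Parameters
    ----------
    body_weight_kg
        Subject body weight.  Volumes are taken verbatim from the
        reference table unless ``scale_volumes`` is set, in which case
        they scale linearly by ``body_weight_kg / 60``.
    overrides
        Optional ``{compartment: {"volume_mL": ..., "flow_fraction": ...}}``
        map; unknown compartments or keys are rejected.
    """
    if body_weight_kg <= 0:
        raise ValueError("body_weight_kg must be > 0")

    scale = body_weight_kg / DEFAULT_BODY_WEIGHT_KG if scale_volumes else 1.0
    volumes = {name: v * (scale if name != "urine" else 1.0)
               for name, v in DEFAULT_VOLUMES_ML.items()}
    fractions = dict(DEFAULT_FLOW_FRACTIONS)

    if overrides:
        for name, fields_ in overrides.items():
            if name not in volumes:
                raise ValueError(f"unknown compartment in overrides: {name!r}")
            for key, value in fields_.items():
                if key == "volume_mL":
                    volumes[name] = float(value)
                elif key == "flow_fraction":
                    if name not in fractions:
                        raise ValueError(
                            f"compartment {name!r} is not perfused; cannot set flow_fraction"
                        )
                    fractions[name] = float(value)
                else:
                    raise ValueError(f"unknown override key {key!r} for {name!r}")
        # Keep the parallel circuit closed: rest-of-body takes up slack.
        others = sum(v for k, v in fractions.items() if k != "rest_of_body")
        if "rest_of_body" not in (overrides or {}):
            fractions["rest_of_body"] = 1.0 - others

    compartments = {
        name: Compartment(
            name=name,
            volume_ml=volumes[name],
            flow_fraction=fractions.get(name, 0.0),
            is_metabolizing=name in _METABOLIZING,
        )
        for name in DEFAULT_VOLUMES_ML
    }

    model = PhysiologyModel(
        compartments=compartments,
        cardiac_output_ml_per_h=cardiac_output_ml_per_h,
        body_weight_kg=body_weight_kg,
        venous_links=set(fractions),
    )
    model.liver_outflow_ml_per_h = model.liver_inflow_ml_per_h
    return model


@dataclass
class TopologyReport:
    """Flow-conservation residuals (fraction of cardiac output) per node."""

    residuals: dict[str, float]
    passed: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"  {node}: {r:.3e}" for node, r in self.residuals.items()]
        status = "PASS" if self.passed else "FAIL"
        return f"topology {status}\n" + "\n".join(lines)


def validate_topology(model: PhysiologyModel, tol: float = 1e-9) -> TopologyReport:
    """Audit flow conservation at the venous pool, liver junction and lungs.

    Raises :class:`TopologyError` if a perfused organ lacks a venous
    return path (directly or via the portal vein).
    """
    co = model.cardiac_output_ml_per_h
    for organ in model.systemic_organs:
        if organ not in model.venous_links:
            raise TopologyError(organ)

    # Liver junction: inflow (hepatic artery + portal) vs recorded outflow.
    liver_in = model.liver_inflow_ml_per_h
    liver_out = model.liver_outflow_ml_per_h
    residual_liver = abs(liver_in - liver_out) / co

    # Venous pool: direct systemic returns + liver outflow vs lung uptake.
    venous_in = liver_out + sum(
        model.organ_flow(o)
        for o in model.systemic_organs
        if o not in model.portal_organs and o != "liver"
    )
    residual_venous = abs(venous_in - co) / co

    # Lungs in series: carry total cardiac output by construction.
    residual_lung = abs(venous_in - co) / co

    # Parallel circuit closure.
    residual_fraction = abs(
        sum(model.compartments[o].flow_fraction for o in model.systemic_organs) - 1.0
    )

    residuals = {
        "liver": residual_liver,
        "venous_blood": residual_venous,
        "lungs": residual_lung,
        "flow_fraction_sum": residual_fraction,
    }
    return TopologyReport(residuals=residuals, passed=max(residuals.values()) < tol)
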