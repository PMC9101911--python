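"""Coupled DEHP/MEHP mass-balance ODE system and its integrator.

Every perfused tissue is flow-limited: the venous outflow of organ *i*
leaves in equilibrium with the tissue at ``C_i / Kp_i``, so

    V_i dC_i/dt = Q_i (C_art - C_i / Kp_i)  (+ inputs, +/- metabolism).

The lungs sit in series on total cardiac output between the venous and
arterial pools; gut, spleen and pancreas drain through the liver.  DEHP
is hydrolysed to MEHP in gut and liver by saturable (Michaelis-Menten)
microsomal and cytosolic reactions, with mass converted by the ratio of
molecular weights so that moles are conserved; MEHP oxidation products
are pooled into a cumulative sink, and MEHP is eliminated into urine
first-order from venous blood with the unbound fraction applied.

State amounts are in micrograms; concentrations are reported as total
tissue amount over anatomical volume (ug/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .chemistry import ChemistrySet, scale_metabolic_capacity
from .dosing import DoseSchedule
from .physiology import PhysiologyModel, PORTAL_ORGANS

__all__ = [
    "ModelOptions",
    "PBPKModel",
    "SimulationResult",
    "BalanceReport",
    "IntegrationError",
    "michaelis_menten_rate",
    "build_model",
    "simulate",
    "mass_balance",
]

SPECIES = ("DEHP", "MEHP")

MG_TO_UG = 1000.0
#: tissue ug/mL -> ug/L, the scale on which Km values are tabulated
UG_PER_ML_TO_UG_PER_L = 1000.0


def michaelis_menten_rate(c_ug_per_l: float, vmax_ug_per_h: float,
                          km_ug_per_l: float) -> float:
    """Saturable reaction velocity v = Vmax * C / (Km + C) in ug/h.

    Returns 0 for a disabled reaction (vmax = 0) regardless of Km.
    """
    if vmax_ug_per_h == 0.0 or c_ug_per_l <= 0.0:
        return 0.0
    return vmax_ug_per_h * c_ug_per_l / (km_ug_per_l + c_ug_per_l)


@dataclass
class ModelOptions:
    """Switches for model variants and diagnostic harnesses.

    ``frozen_arterial`` pins the arterial concentration of a species to
    a constant (ug/mL) and is only meant for equilibration tests;
    ``urine_source`` selects which MEHP pool the first-order urinary
    elimination drains.
    """

    metabolism_enabled: bool = True
    apply_fup_to_tissue: bool = False
    dehp_in_rest_of_body: bool = False
    urine_source: str = "venous_blood"  # or "kidney"
    frozen_arterial: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.urine_source not in ("venous_blood", "kidney"):
            raise ValueError("urine_source must be 'venous_blood' or 'kidney'")


class IntegrationError(RuntimeError):
    """Solver failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time {last_time:.4g} h)")
        self.last_time = last_time


class PBPKModel:
    """Assembled physiology + scaled chemistry, ready to integrate."""

    def __init__(
        self,
        physiology: PhysiologyModel,
        chemistry: ChemistrySet,
        options: ModelOptions | None = None,
        protein_mg_per_g=None,
    ):
        self.physiology = physiology
        self.chemistry = chemistry
        self.options = options or ModelOptions()
        self.vmax_scaled = scale_metabolic_capacity(
            chemistry.reactions, physiology, protein_mg_per_g
        )

        phys = physiology
        self.mw = {s: chemistry.species[s].molecular_weight for s in SPECIES}
        self.mw_ratio = self.mw["MEHP"] / self.mw["DEHP"]

        # Which systemic organs each species distributes into.
        systemic = list(phys.systemic_organs)
        self.organs = {
            "DEHP": [o for o in systemic
                     if o != "rest_of_body" or self.options.dehp_in_rest_of_body],
            "MEHP": systemic,
        }

        # State layout: per species, organs + lungs + arterial + venous;
        # then gut lumen, cumulative urine, cumulative sink.
        self.index: dict[tuple[str, str] | str, int] = {}
        i = 0
        for s in SPECIES:
            for name in self.organs[s] + ["lungs", "arterial_blood", "venous_blood"]:
                self.index[(s, name)] = i
                i += 1
        for name in ("gut_lumen", "urine", "sink"):
            self.index[name] = i
            i += 1
        self.n_states = i

        # Precomputed per-species arrays over non-liver systemic organs.
        self._prep = {}
        co = phys.cardiac_output_ml_per_h
        for s in SPECIES:
            sp = chemistry.species[s]
            others = [o for o in self.organs[s] if o != "liver"]
            idx = np.array([self.index[(s, o)] for o in others])
            Q = np.array([phys.organ_flow(o) for o in others])
            V = np.array([phys.volume(o) for o in others])
            Kp = np.array([sp.kp(o) for o in others])
            portal_mask = np.array([o in phys.portal_organs for o in others])
            q_shunt = co - Q.sum() - phys.organ_flow("liver")
            self._prep[s] = dict(
                organs=others, idx=idx, Q=Q, V=V, Kp=Kp,
                portal=portal_mask, q_shunt=q_shunt,
                kp_liver=sp.kp("liver"), kp_lungs=sp.kp("lungs"),
                i_liver=self.index[(s, "liver")],
                i_lungs=self.index[(s, "lungs")],
                i_art=self.index[(s, "arterial_blood")],
                i_ven=self.index[(s, "venous_blood")],
                skin_pos=others.index("skin"),
            )

        # Metabolic reactions grouped by organ and substrate.
        self._reactions = {"gut": {"DEHP": [], "MEHP": []},
                           "liver": {"DEHP": [], "MEHP": []}}
        for r in chemistry.reactions:
            if r.enabled:
                self._reactions[r.organ][r.substrate].append(
                    (self.vmax_scaled[r.id], r.km_ug_per_l)
                )

    # -- derivative -----------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, schedule: DoseSchedule) -> np.ndarray:
        """Time derivative of the state vector (amounts in ug, t in h)."""
        phys = self.physiology
        opts = self.options
        co = phys.cardiac_output_ml_per_h
        dy = np.zeros_like(y)

        rates = schedule.input_rate(t)
        oral_ug = rates["oral"] * MG_TO_UG
        dermal_ug = rates["dermal"] * MG_TO_UG
        inhal_ug = rates["inhalation"] * MG_TO_UG

        # Gut lumen: oral input, first-order absorption into gut tissue.
        i_lumen = self.index["gut_lumen"]
        absorbed = self.chemistry.kinetics.kgut * y[i_lumen]
        dy[i_lumen] = oral_ug - absorbed

        q_liver_in = phys.liver_inflow_ml_per_h
        q_ha = phys.organ_flow("liver")

        for s in SPECIES:
            p = self._prep[s]
            frozen = s in opts.frozen_arterial
            c_art = (opts.frozen_arterial[s] if frozen
                     else y[p["i_art"]] / phys.volume("arterial_blood"))
            c_ven = y[p["i_ven"]] / phys.volume("venous_blood")
            c_lung_out = y[p["i_lungs"]] / phys.volume("lungs") / p["kp_lungs"]
            c_liver = y[p["i_liver"]] / phys.volume("liver")
            c_liver_out = c_liver / p["kp_liver"]

            c_out = y[p["idx"]] / p["V"] / p["Kp"]
            flux = p["Q"] * (c_art - c_out)
            dy[p["idx"]] += flux

            portal_out = float(np.sum((p["Q"] * c_out)[p["portal"]]))
            direct_out = float(np.sum((p["Q"] * c_out)[~p["portal"]]))

            dy[p["i_liver"]] += q_ha * c_art + portal_out - q_liver_in * c_liver_out
            dy[p["i_ven"]] += (direct_out + q_liver_in * c_liver_out
                               + p["q_shunt"] * c_art - co * c_ven)
            dy[p["i_lungs"]] += co * (c_ven - c_lung_out)
            if not frozen:
                dy[p["i_art"]] += co * (c_lung_out - c_art)
            else:
                dy[p["i_art"]] = 0.0

            if s == "DEHP":
                dy[p["idx"][p["skin_pos"]]] += dermal_ug
                dy[p["i_lungs"]] += inhal_ug
                dy[self.index[("DEHP", "gut")]] += absorbed

        # Saturable metabolism in gut and liver.
        if opts.metabolism_enabled:
            i_sink = self.index["sink"]
            for organ in ("gut", "liver"):
                v_org = phys.volume(organ)
                for s in SPECIES:
                    i_s = self.index[(s, organ)]
                    c_ug_l = y[i_s] / v_org * UG_PER_ML_TO_UG_PER_L
                    total = 0.0
                    for vmax, km in self._reactions[organ][s]:
                        total += michaelis_menten_rate(c_ug_l, vmax, km)
                    if total == 0.0:
                        continue
                    dy[i_s] -= total
                    if s == "DEHP":  # hydrolysis: DEHP -> MEHP, molar
                        dy[self.index[("MEHP", organ)]] += total * self.mw_ratio
                    else:            # oxidation: MEHP -> pooled sink
                        dy[i_sink] += total

        # Urinary elimination of unbound MEHP.
        kurine = self.chemistry.kinetics.kurine
        if kurine > 0:
            src = ("MEHP", "venous_blood" if opts.urine_source == "venous_blood"
                   else "kidney")
            i_src = self.index[src]
            excreted = kurine * self.chemistry.fup_mehp * y[i_src]
            dy[i_src] -= excreted
            dy[self.index["urine"]] += excreted

        return dy


def build_model(
    physiology: PhysiologyModel,
    chemistry: ChemistrySet,
    options: ModelOptions | None = None,
    protein_mg_per_g=None,
) -> PBPKModel:
    """Convenience constructor mirroring :class:`PBPKModel`."""
    return PBPKModel(physiology, chemistry, options, protein_mg_per_g)


@dataclass
class SimulationResult:
    """Dense simulation output.

    ``amounts`` is (n_times, n_states) in ug; concentration accessors
    divide by anatomical volumes.  Cumulative urine and sink series are
    reported in mg.
    """

    time_h: np.ndarray
    amounts: np.ndarray
    model: PBPKModel
    schedule: DoseSchedule
    diagnostics: dict = field(default_factory=dict)

    def amount(self, species: str, compartment: str) -> np.ndarray:
        """Amount series (ug) for one species in one compartment."""
        return self.amounts[:, self.model.index[(species, compartment)]]

    def concentration(self, species: str, organ: str) -> np.ndarray:
        """Concentration series (ug/mL): total amount / anatomical volume.

        ``organ`` may be a '+'-joined combination (e.g.
        ``"spleen+pancreas"``), reported as the volume-weighted combined
        concentration.
        """
        parts = [p.strip() for p in organ.split("+")]
        for p in parts:
            if (species, p) not in self.model.index:
                raise KeyError(f"no {species} state in compartment {p!r}")
        total = sum(self.amount(species, p) for p in parts)
        volume = sum(self.model.physiology.volume(p) for p in parts)
        return total / volume

    @property
    def gut_lumen_ug(self) -> np.ndarray:
        return self.amounts[:, self.model.index["gut_lumen"]]

    @property
    def cumulative_urine_mg(self) -> np.ndarray:
        return self.amounts[:, self.model.index["urine"]] / MG_TO_UG

    @property
    def cumulative_sink_mg(self) -> np.ndarray:
        return self.amounts[:, self.model.index["sink"]] / MG_TO_UG

    def body_burden_ug(self) -> np.ndarray:
        """Whole-body burden: all DEHP + MEHP tissue amounts plus the
        unabsorbed gut lumen; urine and sink are excluded."""
        cols = [i for key, i in self.model.index.items()
                if isinstance(key, tuple) or key == "gut_lumen"]
        return self.amounts[:, cols].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_h, compartment, species, amount_ug,
        concentration_ug_per_mL (sorted, deterministic order)."""
        rows = []
        for key in sorted(k for k in self.model.index if isinstance(k, tuple)):
            species, comp = key
            amt = self.amount(species, comp)
            conc = amt / self.model.physiology.volume(comp)
            rows.append(pd.DataFrame({
                "time_h": self.time_h,
                "compartment": comp,
                "species": species,
                "amount_ug": amt,
                "concentration_ug_per_mL": conc,
            }))
        for name in ("gut_lumen", "urine", "sink"):
            amt = self.amounts[:, self.model.index[name]]
            rows.append(pd.DataFrame({
                "time_h": self.time_h,
                "compartment": name,
                "species": "DEHP" if name == "gut_lumen" else "MEHP",
                "amount_ug": amt,
                "concentration_ug_per_mL": np.nan,
            }))
        return pd.concat(rows, ignore_index=True)


def simulate(
    model: PBPKModel,
    schedule: DoseSchedule,
    t_end_h: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    points_per_h: int = 20,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the system over [0, t_end_h].

    Integration restarts at every dose on/off boundary so the solver
    never steps across a rate discontinuity; output is a uniform grid
    of ``points_per_h`` samples per hour.
    """
    if t_end_h <= 0:
        raise ValueError("t_end_h must be > 0")

    grid = np.round(np.arange(0.0, t_end_h * points_per_h + 0.5) / points_per_h, 10)
    grid = grid[grid <= t_end_h]
    boundaries = schedule.boundaries(t_end_h)

    y = np.zeros(model.n_states)
    times = [0.0]
    states = [y.copy()]
    n_rhs = 0
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        t_eval = grid[(grid > a) & (grid < b)]
        t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(
            model.rhs, (a, b), y, method=method, rtol=rtol, atol=atol,
            t_eval=t_eval, args=(schedule,), dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(sol.message, last_time=float(sol.t[-1]) if len(sol.t) else a)
        n_rhs += sol.nfev
        times.extend(sol.t.tolist())
        states.extend(sol.y.T)
        y = sol.y[:, -1].copy()
        if not np.all(np.isfinite(y)):
            raise IntegrationError("non-finite state", last_time=float(b))

    time_h = np.array(times)
    amounts = np.vstack(states)
    # Deduplicate boundary points that coincide with grid points.
    keep = np.concatenate([[True], np.diff(time_h) > 1e-12])
    time_h, amounts = time_h[keep], amounts[keep]

    min_amount = float(amounts.min())
    if min_amount < -1e-6:
        raise IntegrationError(
            f"state went negative beyond tolerance ({min_amount:.3e} ug)",
            last_time=float(time_h[-1]),
        )
    result = SimulationResult(
        time_h=time_h, amounts=amounts, model=model, schedule=schedule,
        diagnostics={"n_rhs_evaluations": n_rhs, "min_state_ug": min_amount,
                     "method": method, "rtol": rtol, "atol": atol},
    )
    result.diagnostics["mass_balance_residual"] = mass_balance(result).worst_residual
    return result


@dataclass
class BalanceReport:
    """Molar conservation audit of a completed run."""

    worst_residual: float
    worst_time_h: float
    passed: bool


def mass_balance(result: SimulationResult, tol: float = 1e-6) -> BalanceReport:
    """Check molar conservation at every reported time.

    Cumulative molar input must equal DEHP moles in the body (tissues +
    gut lumen) plus MEHP-equivalent moles (tissues + urine + sink).
    """
    model = result.model
    mw_dehp, mw_mehp = model.mw["DEHP"], model.mw["MEHP"]

    dehp_cols = [i for k, i in model.index.items()
                 if isinstance(k, tuple) and k[0] == "DEHP"]
    mehp_cols = [i for k, i in model.index.items()
                 if isinstance(k, tuple) and k[0] == "MEHP"]
    dehp_ug = result.amounts[:, dehp_cols].sum(axis=1) + result.gut_lumen_ug
    mehp_ug = (result.amounts[:, mehp_cols].sum(axis=1)
               + result.amounts[:, model.index["urine"]]
               + result.amounts[:, model.index["sink"]])
    body_moles = dehp_ug / mw_dehp + mehp_ug / mw_mehp

    input_ug = np.asarray(result.schedule.cumulative_input_mg(result.time_h)) * MG_TO_UG
    input_moles = input_ug / mw_dehp

    scale = max(float(input_moles.max()), 1e-30)
    residual = np.abs(body_moles - input_moles) / scale
    worst = int(np.argmax(residual))
    return BalanceReport(
        worst_residual=float(residual[worst]),
        worst_time_h=float(result.time_h[worst]),
        passed=float(residual[worst]) < tol,
    )
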