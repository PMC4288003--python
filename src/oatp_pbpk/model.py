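"""Whole-body PBPK model with enterohepatic recirculation.

The body is represented by ten anatomical compartments.  Lung, gut,
spleen, kidney and rest-of-body are perfusion-limited (well stirred, with
tissue:plasma partition coefficient Kp).  Liver, muscle and adipose are
permeability-limited: an extracellular (vascular) space in the blood path
exchanges with an intracellular space through a bidirectional passive
diffusion clearance acting on unbound concentrations.  The liver is split
into ``n`` serial sub-units, each a pair of liver-blood and liver-tissue
compartments; active uptake (CL_act,tot), passive diffusion
(CL_pass,liver) and biliary excretion (CL_bile) are divided equally
across sub-units.

Enterohepatic recirculation: biliary excretion feeds a bile-duct
compartment (volume 0.318% of liver) that empties continuously into the
GI lumen at the bile flow rate (350 mL/day by default); lumen drug is
absorbed into the portal inflow of liver sub-unit 1 at rate
``ka * FaFg * X_lumen`` while the remainder, ``ka * (1 - FaFg) *
X_lumen``, is lost to an unabsorbed (fecal) sink.  Both the initial oral
dose and biliary-recirculated drug share the same Fa*Fg split.
Gallbladder storage is not modeled (continuous bile flow).

The system is linear with piecewise-constant input, so two integration
routes are provided: a stiff ODE solver (LSODA; default) and an exact
matrix-exponential propagator over the output grid (``method="expm"``),
which the fitting loop uses for speed.  Either route serves as an
independent numerical cross-check of the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .specs import CompoundSpec, ConfigurationError, DoseRegimen, PhysiologySpec

__all__ = [
    "PBPKModel",
    "SimulationResult",
    "SimulationError",
    "build_model",
    "simulate",
    "pk_metrics",
]


class SimulationError(RuntimeError):
    """The ODE integration failed or produced an unphysical state."""


@dataclass
class StateLayout:
    """Index bookkeeping for the state vector (amounts in ng)."""

    n_liver: int

    def __post_init__(self) -> None:
        n = self.n_liver
        names = [
            "venous_blood", "arterial_blood", "lung",
            "adipose_ec", "adipose_ic", "muscle_ec", "muscle_ic",
            "gut", "spleen", "kidney", "rest_of_body",
        ]
        self.liver_blood = []
        self.liver_tissue = []
        for i in range(n):
            self.liver_blood.append(len(names))
            names.append(f"liver_blood_{i + 1}")
            self.liver_tissue.append(len(names))
            names.append(f"liver_tissue_{i + 1}")
        self.bile = len(names)
        names.append("bile")
        self.lumen = len(names)
        names.append("lumen")
        self.renal_elim = len(names)
        names.append("renal_eliminated")
        self.unabsorbed = len(names)
        names.append("unabsorbed")
        self.names = names
        self.n_states = len(names)

    # fixed indices
    VEN, ART, LUNG = 0, 1, 2
    ADI_EC, ADI_IC, MUS_EC, MUS_IC = 3, 4, 5, 6
    GUT, SPL, KID, ROB = 7, 8, 9, 10


class PBPKModel:
    """A compound + physiology bound into a linear ODE system.

    The model exposes the right-hand side (``rhs``), the constant system
    matrix ``A`` (d amounts/dt = A x + input), and :meth:`simulate`.
    """

    def __init__(self, compound: CompoundSpec, physiology: PhysiologySpec):
        self.compound = compound
        self.physiology = physiology
        self.layout = StateLayout(physiology.n_liver_subunits)
        self._A = self._build_matrix()

    # ------------------------------------------------------------------
    # system construction
    # ------------------------------------------------------------------
    def _volumes(self) -> np.ndarray:
        p, L = self.physiology, self.layout
        vol = np.empty(L.n_states)
        tv = p.tissue_volumes
        vol[L.VEN] = p.volume_venous_blood
        vol[L.ART] = p.volume_arterial_blood
        vol[L.LUNG] = tv["lung"]
        vol[L.ADI_EC] = p.ec_fraction_adipose * tv["adipose"]
        vol[L.ADI_IC] = (1 - p.ec_fraction_adipose) * tv["adipose"]
        vol[L.MUS_EC] = p.ec_fraction_muscle * tv["muscle"]
        vol[L.MUS_IC] = (1 - p.ec_fraction_muscle) * tv["muscle"]
        vol[L.GUT] = tv["gut"]
        vol[L.SPL] = tv["spleen"]
        vol[L.KID] = tv["kidney"]
        vol[L.ROB] = tv["rest_of_body"]
        n = p.n_liver_subunits
        v_lb = p.liver_blood_fraction * tv["liver"] / n
        v_lt = (1 - p.liver_blood_fraction) * tv["liver"] / n
        for i in range(n):
            vol[L.liver_blood[i]] = v_lb
            vol[L.liver_tissue[i]] = v_lt
        vol[L.bile] = p.V_bile
        vol[L.lumen] = 1.0  # lumen tracked as amount; volume unused
        vol[L.renal_elim] = 1.0
        vol[L.unabsorbed] = 1.0
        return vol

    def _build_matrix(self) -> np.ndarray:
        c, p, L = self.compound, self.physiology, self.layout
        vol = self._volumes()
        self.volumes = vol
        n = p.n_liver_subunits
        q = p.tissue_blood_flows
        Q_co = q["lung"]
        Q_h = p.Q_liver_total
        A = np.zeros((L.n_states, L.n_states))

        def add_flow(src: int, dst: int | None, rate_conc: float) -> None:
            """Transfer at `rate_conc` L/h acting on C_src = X_src / V_src."""
            k = rate_conc / vol[src]
            A[src, src] -= k
            if dst is not None:
                A[dst, src] += k

        fu_ec = c.fu_p / c.RB_P  # unbound fraction referred to blood conc

        # venous blood -> lung -> arterial blood
        add_flow(L.VEN, L.LUNG, Q_co)
        add_flow(L.LUNG, L.ART, Q_co * c.RB_P / c.Kp["lung"])
        # renal elimination from venous plasma
        add_flow(L.VEN, L.renal_elim, c.CL_renal / c.RB_P)

        # perfusion-limited systemic tissues (kidney, rest): art -> tissue -> ven
        for t, idx in (("kidney", L.KID), ("rest_of_body", L.ROB)):
            add_flow(L.ART, idx, q[t])
            add_flow(idx, L.VEN, q[t] * c.RB_P / c.Kp[t])
        # splanchnic tissues drain to the portal vein (liver sub-unit 1)
        for t, idx in (("gut", L.GUT), ("spleen", L.SPL)):
            add_flow(L.ART, idx, q[t])
            add_flow(idx, L.liver_blood[0], q[t] * c.RB_P / c.Kp[t])

        # permeability-limited muscle / adipose
        for t, ec, ic, ratio in (
            ("muscle", L.MUS_EC, L.MUS_IC, c.pass_ratio_muscle),
            ("adipose", L.ADI_EC, L.ADI_IC, c.pass_ratio_adipose),
        ):
            add_flow(L.ART, ec, q[t])
            add_flow(ec, L.VEN, q[t])
            cl_pass = ratio * c.CL_pass_liver
            # influx on unbound plasma in EC, efflux on unbound IC
            add_flow(ec, ic, cl_pass * fu_ec)
            add_flow(ic, ec, cl_pass * c.fu_p / c.Kp[t])

        # liver: hepatic artery joins portal inflow at sub-unit 1
        add_flow(L.ART, L.liver_blood[0], q["liver"])
        cl_up = (c.CL_act_tot + c.CL_pass_liver) / n
        cl_eff = c.CL_pass_liver / n
        cl_bile = c.CL_bile / n
        for i in range(n):
            lb, lt = L.liver_blood[i], L.liver_tissue[i]
            nxt = L.liver_blood[i + 1] if i + 1 < n else L.VEN
            add_flow(lb, nxt, Q_h)
            add_flow(lb, lt, cl_up * fu_ec)
            add_flow(lt, lb, cl_eff * c.fu_liver)
            add_flow(lt, L.bile, cl_bile * c.fu_liver)

        # bile empties into GI lumen
        add_flow(L.bile, L.lumen, p.Q_liver_bile)
        # lumen: absorbed fraction to portal inflow, remainder to sink
        k_abs = c.ka * c.FaFg
        k_loss = c.ka * (1.0 - c.FaFg)
        A[L.lumen, L.lumen] -= c.ka
        A[L.liver_blood[0], L.lumen] += k_abs
        A[L.unabsorbed, L.lumen] += k_loss
        return A

    @property
    def A(self) -> np.ndarray:
        """System matrix of the linear ODE d(amounts)/dt = A @ x + u(t)."""
        return self._A

    def rhs(self, t: float, x: np.ndarray,
            infusion_rate: float = 0.0) -> np.ndarray:
        """Right-hand side; `infusion_rate` (ng/h) enters venous blood."""
        dx = self._A @ x
        dx[self.layout.VEN] += infusion_rate
        return dx

    # ------------------------------------------------------------------
    # simulation
    # ------------------------------------------------------------------
    def simulate(
        self,
        regimen: DoseRegimen,
        time_grid: np.ndarray,
        rel_tol: float = 1e-8,
        abs_tol: float = 1e-10,
        method: str = "lsoda",
    ) -> "SimulationResult":
        """Simulate the regimen over ``time_grid`` (hours).

        ``method="lsoda"`` uses the stiff-capable LSODA integrator with
        the given tolerances; ``method="expm"`` propagates the exact
        solution of the linear system segment-by-segment via the matrix
        exponential (tolerances are then irrelevant).
        """
        t = np.asarray(time_grid, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time_grid must be strictly increasing, size >= 2")
        if rel_tol <= 0 or abs_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if t[0] > regimen.start_time or t[-1] < regimen.end_time:
            raise ValueError("time_grid must cover the dosing events")

        L = self.layout
        # piecewise-constant input segments: (t0, t1, infusion_rate)
        events = sorted({t[0], t[-1], regimen.start_time, regimen.end_time})
        segments = []
        for a, b in zip(events[:-1], events[1:]):
            rate = 0.0
            if (regimen.route == "iv_infusion"
                    and a >= regimen.start_time - 1e-12
                    and b <= regimen.end_time + 1e-12):
                rate = regimen.dose_ng / regimen.infusion_duration
            segments.append((a, b, rate))

        x0 = np.zeros(L.n_states)
        traj = np.zeros((t.size, L.n_states))
        if t[0] == regimen.start_time and regimen.route == "oral":
            x0[L.lumen] += regimen.dose_ng
        traj[0] = x0

        x = x0.copy()
        for a, b, rate in segments:
            if regimen.route == "oral" and a == regimen.start_time and a != t[0]:
                x[L.lumen] += regimen.dose_ng
            mask = (t > a) & (t <= b)
            t_out = t[mask]
            if method == "expm":
                x, xs = _propagate_expm(self._A, x, a, b, t_out, rate, L.VEN)
            elif method == "lsoda":
                x, xs = _propagate_lsoda(self, x, a, b, t_out, rate,
                                         rel_tol, abs_tol)
            else:
                raise ValueError(f"unknown method {method!r}")
            traj[mask] = xs
            idx0 = np.nonzero(t == a)[0]
            if idx0.size and a != t[0]:
                pass  # value at segment start was written by previous segment

        return self._package(regimen, t, traj, abs_tol)

    def _package(self, regimen, t, traj, abs_tol) -> "SimulationResult":
        L, c = self.layout, self.compound
        neg = traj.min()
        if neg < -1e4 * max(abs_tol, 1e-12) - 1e-6 * traj.max():
            raise SimulationError(
                f"negative state amount {neg:.3g} ng beyond tolerance; "
                "try tighter rel_tol/abs_tol"
            )
        traj = np.where(traj < 0, 0.0, traj)
        v_ven = self.volumes[L.VEN]
        plasma = traj[:, L.VEN] / v_ven / c.RB_P / 1.0e3  # ng/mL
        v_lt = self.volumes[[*L.liver_tissue]]
        liver = traj[:, L.liver_tissue].sum(axis=1) / v_lt.sum() / 1.0e3
        eliminated = {
            "renal": traj[:, L.renal_elim].copy(),
            "unabsorbed": traj[:, L.unabsorbed].copy(),
        }
        return SimulationResult(
            time_grid=t.copy(),
            plasma_conc=plasma,
            liver_conc=liver,
            state_amounts=traj,
            state_names=list(L.names),
            eliminated=eliminated,
            regimen=regimen,
            model=self,
        )


def _propagate_expm(A, x, a, b, t_out, rate, ven_idx):
    """Exact propagation of dx/dt = A x + u over [a, b], u constant."""
    n = A.shape[0]
    if rate != 0.0:
        # augment with a constant-input state: z = [x; 1]
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = A
        M[ven_idx, n] = rate
        z = np.append(x, 1.0)
    else:
        M, z = A, x
    times = np.concatenate([t_out, [b]]) if (t_out.size == 0 or t_out[-1] != b) \
        else t_out
    xs = np.empty((t_out.size, n))
    prev = a
    cache: dict[float, np.ndarray] = {}
    for j, tj in enumerate(times):
        dt = tj - prev
        if dt > 0:
            P = cache.get(dt)
            if P is None:
                P = expm(M * dt)
                cache[dt] = P
            z = P @ z
        prev = tj
        if j < t_out.size:
            xs[j] = z[:n]
    return (z[:n].copy() if rate != 0.0 else z.copy()), xs


def _propagate_lsoda(model, x, a, b, t_out, rate, rel_tol, abs_tol):
    need_end = t_out.size == 0 or t_out[-1] != b
    t_eval = np.concatenate([t_out, [b]]) if need_end else t_out
    sol = solve_ivp(
        model.rhs, (a, b), x, method="LSODA", t_eval=t_eval,
        rtol=rel_tol, atol=abs_tol, args=(rate,),
    )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed at t = {sol.t[-1] if sol.t.size else a:g} h: "
            f"{sol.message}"
        )
    ys = sol.y.T
    x_end = ys[-1]
    xs = ys[:-1] if need_end else ys
    return x_end.copy(), xs


@dataclass
class SimulationResult:
    """Simulated traces: plasma and intracellular-liver concentrations
    (ng/mL), per-compartment amounts (ng), and cumulative eliminations."""

    time_grid: np.ndarray
    plasma_conc: np.ndarray
    liver_conc: np.ndarray
    state_amounts: np.ndarray
    state_names: list
    eliminated: Mapping[str, np.ndarray]
    regimen: DoseRegimen | None = None
    model: PBPKModel | None = None

    def amount(self, name: str) -> np.ndarray:
        """Amount trace (ng) for a named compartment."""
        return self.state_amounts[:, self.state_names.index(name)]

    def total_in_body(self) -> np.ndarray:
        """Total drug amount in the body (ng), including bile and lumen."""
        drop = {self.state_names.index("renal_eliminated"),
                self.state_names.index("unabsorbed")}
        keep = [i for i in range(len(self.state_names)) if i not in drop]
        return self.state_amounts[:, keep].sum(axis=1)

    def mass_balance_error(self) -> np.ndarray:
        """dose - (body + renal + unabsorbed), per time point (ng)."""
        dosed = np.zeros_like(self.time_grid)
        if self.regimen is not None:
            r = self.regimen
            if r.route == "oral":
                dosed = np.where(self.time_grid >= r.start_time, r.dose_ng, 0.0)
            else:
                frac = np.clip(
                    (self.time_grid - r.start_time) / r.infusion_duration,
                    0.0, 1.0)
                dosed = r.dose_ng * frac
        total = (self.total_in_body()
                 + self.eliminated["renal"] + self.eliminated["unabsorbed"])
        return dosed - total

    def pk_metrics(self, t_start: float | None = None,
                   t_end: float | None = None) -> dict:
        return pk_metrics(self, t_start, t_end)

    def to_frame(self):
        """Long-form trace as a pandas DataFrame (time_h, plasma, liver)."""
        import pandas as pd

        return pd.DataFrame({
            "time_h": self.time_grid,
            "plasma_ng_per_mL": self.plasma_conc,
            "liver_ng_per_mL": self.liver_conc,
        })

    def amounts_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.state_amounts, columns=self.state_names)
        df.insert(0, "time_h", self.time_grid)
        return df

    def plot(self, ax=None, log_scale: bool = True, label: str | None = None):
        """Plasma (solid) and liver (dashed) concentration profiles."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.time_grid, self.plasma_conc, "-",
                label=(label or "plasma"))
        ax.plot(self.time_grid, self.liver_conc, "--",
                label=(label + " (liver)") if label else "liver")
        if log_scale:
            ax.set_yscale("log")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (ng/mL)")
        ax.legend()
        return ax


# ----------------------------------------------------------------------
# functional façade
# ----------------------------------------------------------------------
def build_model(compound: CompoundSpec,
                physiology: PhysiologySpec) -> PBPKModel:
    """Construct the ODE system handle for a compound in a physiology."""
    return PBPKModel(compound, physiology)


def simulate(
    compound: CompoundSpec,
    physiology: PhysiologySpec,
    regimen: DoseRegimen,
    time_grid: np.ndarray,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
    method: str = "lsoda",
) -> SimulationResult:
    """One-call simulation; see :meth:`PBPKModel.simulate`."""
    return PBPKModel(compound, physiology).simulate(
        regimen, time_grid, rel_tol=rel_tol, abs_tol=abs_tol, method=method
    )


def pk_metrics(result: SimulationResult,
               t_start: float | None = None,
               t_end: float | None = None,
               trace: str = "plasma") -> dict:
    """AUC (trapezoid), Cmax and tmax of a trace over [t_start, t_end].

    Ties in Cmax resolve to the first occurrence.  AUC carries units
    ng·h/mL.
    """
    t = result.time_grid
    y = result.plasma_conc if trace == "plasma" else result.liver_conc
    t0 = t[0] if t_start is None else t_start
    t1 = t[-1] if t_end is None else t_end
    if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
        raise ValueError("window outside the simulated range")
    mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
    tw, yw = t[mask], y[mask]
    if tw.size < 2:
        raise ValueError("window must contain at least 2 grid points")
    auc = float(np.trapezoid(yw, tw))
    imax = int(np.argmax(yw))
    return {"AUC": auc, "Cmax": float(yw[imax]), "tmax": float(tw[imax])}
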