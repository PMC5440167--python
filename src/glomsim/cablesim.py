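"""Passive compartmental simulation and EPSP measurement protocols.

The model is the standard passive cable tree: isopotential compartments with
specific membrane resistance R_m (kΩ·cm²), capacitance C_m (µF/cm²) and axial
resistivity R_a (Ω·cm), coupled by axial conductances and driven by synaptic
conductance transients g(t)·(E_syn − V).  Integration uses backward Euler with
Hines-ordered elimination (unconditionally stable, O(n) per step); the
synaptic conductance is evaluated at the step start.

Internal electrical units: mV, ms, µS, nF, nA — so ΔV/ΔI comes out in MΩ.

Measurement protocols mirror standard practice for quantifying synaptic
integration: mEPSP (one synapse in isolation, recorded at the soma and at the
synapse's own compartment), uEPSP (all synapses of one afferent activated
synchronously), attenuation (somatic/dendritic mEPSP amplitude) and summation
efficacy (uEPSP over the linear sum of somatic mEPSPs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from . import _hines
from .morphology import CompartmentalModel

__all__ = [
    "MembraneParams",
    "SynapseParams",
    "SynapseSite",
    "VoltageTrace",
    "membrane_preset",
    "conductance_waveform",
    "conductance_peak_time",
    "simulate",
    "measure_mepsps",
    "measure_uepsp",
    "summation_efficacy",
    "input_resistance",
    "input_resistance_per_cable",
    "time_averaged_voltage",
    "somatic_unit_kernels",
    "DEFAULT_GMAX_NS",
    "EQUALIZED_GMAX_NS",
]

#: peak synaptic conductance producing realistic (~5 mV) unitary EPSPs
DEFAULT_GMAX_NS = 0.1
#: reduced conductance that keeps mean uEPSPs fixed after synapse-count equalization
EQUALIZED_GMAX_NS = 0.0958


@dataclass(frozen=True)
class MembraneParams:
    """Specific passive membrane parameters.

    r_m: kΩ·cm²; c_m: µF/cm²; r_a: Ω·cm; e_rest: mV.  The resting potential
    only sets the synaptic driving force — all amplitude measures are
    differences from rest.
    """

    r_m: float = 20.8
    c_m: float = 0.8
    r_a: float = 266.1
    e_rest: float = -60.0

    def __post_init__(self) -> None:
        if min(self.r_m, self.c_m, self.r_a) <= 0:
            raise ValueError("specific membrane parameters must be positive")

    @property
    def tau_m(self) -> float:
        """Membrane time constant R_m·C_m in ms."""
        return self.r_m * self.c_m


_PRESETS = {"cell3": MembraneParams(r_m=20.8, c_m=0.8, r_a=266.1)}


def membrane_preset(name: str, **overrides) -> MembraneParams:
    """Named membrane parameter sets fitted to antennal-lobe projection neurons.

    Only the 'cell3' fit has published values; 'cell1' and 'cell2' must be
    supplied explicitly (pass r_m, c_m, r_a as overrides).
    """
    if name in _PRESETS:
        return replace(_PRESETS[name], **overrides) if overrides else _PRESETS[name]
    if name in ("cell1", "cell2"):
        required = {"r_m", "c_m", "r_a"}
        if not required.issubset(overrides):
            raise ValueError(
                f"preset {name!r} has no published values; supply r_m, c_m and r_a"
            )
        return MembraneParams(**overrides)
    raise KeyError(f"unknown membrane preset {name!r}")


@dataclass(frozen=True)
class SynapseParams:
    """Double-exponential synaptic conductance.

    g_max: nS (peak); tau_rise/tau_decay: ms; e_syn: mV (cholinergic
    receptor-neuron synapses reverse near 0 mV).
    """

    g_max: float = DEFAULT_GMAX_NS
    tau_rise: float = 0.2
    tau_decay: float = 1.1
    e_syn: float = 0.0

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if not (self.tau_decay >= self.tau_rise > 0):
            raise ValueError("need tau_decay >= tau_rise > 0")


@dataclass(frozen=True)
class SynapseSite:
    """One afferent synapse bound to a compartment of a target neuron."""

    orn_id: str
    pn_id: str
    compartment_index: int
    site_id: int
    cable_index: int = -1
    offset: float = 0.0        # µm along the cable


@dataclass
class VoltageTrace:
    """Voltage at one recording compartment on a uniform time grid."""

    times: np.ndarray          # ms
    values: np.ndarray         # mV
    e_rest: float

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def amplitude(self) -> float:
        """Peak depolarization above rest (pre-event baseline)."""
        return float(self.values.max() - self.e_rest)


def conductance_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the conductance peak: (τ_r·τ_d/(τ_d−τ_r))·ln(τ_d/τ_r)."""
    if math.isclose(tau_rise, tau_decay, rel_tol=1e-9):
        return tau_rise  # alpha-function limit: peak at τ
    return tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)


def conductance_waveform(t, p: SynapseParams):
    """g(t) in nS for an event at t=0; zero for t<0, peak equal to g_max."""
    t = np.asarray(t, dtype=float)
    if math.isclose(p.tau_rise, p.tau_decay, rel_tol=1e-9):
        # alpha-function limit of the double exponential
        g = p.g_max * (t / p.tau_rise) * np.exp(1.0 - t / p.tau_rise)
    else:
        tstar = conductance_peak_time(p.tau_rise, p.tau_decay)
        norm = math.exp(-tstar / p.tau_decay) - math.exp(-tstar / p.tau_rise)
        g = p.g_max / norm * (np.exp(-t / p.tau_decay) - np.exp(-t / p.tau_rise))
    return np.where(t >= 0, g, 0.0)


# ---------------------------------------------------------------------------
# electrical assembly


def _electrical_arrays(model: CompartmentalModel):
    """Per-compartment capacitance (nF), leak (µS) and axial conductance (µS)."""
    mem = model.membrane
    cap = mem.c_m * model.area * 1e-5               # µF/cm² × µm² → nF
    g_leak = model.area * 1e-5 / mem.r_m            # µm²/(kΩ·cm²) → µS
    # axial conductance between compartment centres: half-resistances in series
    half_r = mem.r_a * (model.length / 2.0) / (math.pi * (model.diameter / 2.0) ** 2) * 1e4  # Ω
    g_ax = np.zeros(model.n_compartments)
    p = model.parent
    for i in range(1, model.n_compartments):
        g_ax[i] = 1e6 / (half_r[i] + half_r[p[i]])  # Ω → µS
    return cap, g_leak, g_ax


def _waveform_samples(p: SynapseParams, dt: float) -> np.ndarray:
    """Normalized waveform sampled at dt, truncated once negligible."""
    t_end = max(20.0 * p.tau_decay, 5.0 * dt)
    t = np.arange(0.0, t_end, dt)
    if p.g_max == 0:
        return np.zeros(len(t))
    return conductance_waveform(t, p) / p.g_max


def _as_comp(site) -> int:
    return site.compartment_index if isinstance(site, SynapseSite) else int(site)


def simulate(
    model: CompartmentalModel,
    events,
    syn: SynapseParams,
    duration: float,
    dt: float = 0.025,
    record_at="soma",
    i_inj: tuple[int, float] | None = None,
):
    """Integrate the tree and return voltage trace(s).

    events: iterable of (site-or-compartment, onset ms).  record_at: 'soma',
    a compartment index, or a sequence of indices (then a list of traces is
    returned).  i_inj: optional (compartment, amplitude nA) step current
    switched on at t=0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cap, g_leak, g_ax = _electrical_arrays(model)
    ev = list(events)
    ev_comp = np.array([_as_comp(s) for s, _ in ev], dtype=np.int64)
    if len(ev_comp) and (ev_comp.min() < 0 or ev_comp.max() >= model.n_compartments):
        raise ValueError("synapse site bound to an invalid compartment")
    ev_start = np.array([int(round(t0 / dt)) for _, t0 in ev], dtype=np.int64)
    ev_g = np.full(len(ev), syn.g_max * 1e-3)       # nS → µS
    wave = _waveform_samples(syn, dt)
    n_steps = int(round(duration / dt))

    single = record_at == "soma" or np.isscalar(record_at)
    if record_at == "soma":
        rec = np.array([model.soma_index], dtype=np.int64)
    else:
        rec = np.atleast_1d(np.asarray(record_at, dtype=np.int64))

    inj_comp, inj_amp = (-1, 0.0) if i_inj is None else (int(i_inj[0]), float(i_inj[1]))
    out = _hines.integrate(
        model.parent.astype(np.int64), g_ax, g_leak, cap,
        float(dt), float(model.membrane.e_rest), float(syn.e_syn),
        ev_comp, ev_start, ev_g, wave,
        inj_comp, inj_amp, n_steps, rec,
    )
    if not np.isfinite(out).all():
        bad = int(np.argwhere(~np.isfinite(out))[0, 0])
        raise FloatingPointError(f"non-finite voltage at step {bad}")
    times = np.arange(n_steps + 1) * dt
    traces = [VoltageTrace(times, out[:, j].copy(), model.membrane.e_rest) for j in range(out.shape[1])]
    return traces[0] if single else traces


def measure_mepsps(
    model: CompartmentalModel,
    sites,
    syn: SynapseParams,
    duration: float = 50.0,
    dt: float = 0.025,
) -> pd.DataFrame:
    """Miniature EPSP of every site in isolation.

    One synaptic event per site, with the others silent; amplitudes are peak
    depolarizations above rest at the soma and at the site's own compartment.
    attenuation = somatic/dendritic amplitude ∈ (0, 1].
    """
    sites = list(sites)
    if not sites:
        raise ValueError("need at least one synapse site")
    comps = np.array([_as_comp(s) for s in sites])
    rows = {}
    for c in np.unique(comps):
        trs = simulate(model, [(int(c), 0.0)], syn, duration, dt,
                       record_at=[model.soma_index, int(c)])
        rows[int(c)] = (trs[0].amplitude(), trs[1].amplitude())
    rec = []
    for s, c in zip(sites, comps):
        som, den = rows[int(c)]
        rec.append(
            {
                "site_id": s.site_id if isinstance(s, SynapseSite) else int(c),
                "orn_id": s.orn_id if isinstance(s, SynapseSite) else None,
                "compartment": int(c),
                "somatic_mv": som,
                "dendritic_mv": den,
                "attenuation": som / den if den > 0 else np.nan,
            }
        )
    return pd.DataFrame(rec)


def measure_uepsp(
    model: CompartmentalModel,
    sites_of_one_orn,
    syn: SynapseParams,
    duration: float = 50.0,
    dt: float = 0.025,
) -> float:
    """Somatic peak response to synchronous activation of all given sites (mV)."""
    sites = list(sites_of_one_orn)
    if not sites:
        raise ValueError("need at least one synapse site")
    tr = simulate(model, [(s, 0.0) for s in sites], syn, duration, dt)
    return tr.amplitude()


def summation_efficacy(
    model: CompartmentalModel,
    sites_of_one_orn,
    syn: SynapseParams,
    duration: float = 50.0,
    dt: float = 0.025,
    mepsp_table: pd.DataFrame | None = None,
) -> float:
    """uEPSP divided by the linear sum of its somatic mEPSPs (∈ (0, 1])."""
    sites = list(sites_of_one_orn)
    u = measure_uepsp(model, sites, syn, duration, dt)
    if mepsp_table is None:
        mepsp_table = measure_mepsps(model, sites, syn, duration, dt)
        mepsp_sum = float(mepsp_table["somatic_mv"].sum())
    else:
        comps = [_as_comp(s) for s in sites]
        per_comp = mepsp_table.drop_duplicates("compartment").set_index("compartment")["somatic_mv"]
        mepsp_sum = float(per_comp.loc[comps].sum())
    return u / mepsp_sum


def _conductance_matrix(model: CompartmentalModel) -> sparse.csc_matrix:
    cap, g_leak, g_ax = _electrical_arrays(model)
    n = model.n_compartments
    p = model.parent
    rows, cols, vals = [], [], []
    diag = g_leak.copy()
    for i in range(1, n):
        diag[i] += g_ax[i]
        diag[p[i]] += g_ax[i]
        rows += [i, p[i]]
        cols += [p[i], i]
        vals += [-g_ax[i], -g_ax[i]]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    return sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))


def input_resistance(model: CompartmentalModel, compartment: int) -> float:
    """Steady-state input resistance ΔV/ΔI at a compartment, in MΩ."""
    G = _conductance_matrix(model)
    rhs = np.zeros(model.n_compartments)
    rhs[compartment] = 1.0                           # 1 nA
    dv = splu(G).solve(rhs)
    return float(dv[compartment])                    # mV/nA = MΩ


def transfer_resistance(model: CompartmentalModel, i: int, j: int) -> float:
    """Steady-state transfer resistance: voltage at j per unit current at i (MΩ)."""
    G = _conductance_matrix(model)
    rhs = np.zeros(model.n_compartments)
    rhs[i] = 1.0
    return float(splu(G).solve(rhs)[j])


def input_resistance_per_cable(model: CompartmentalModel) -> pd.DataFrame:
    """Input resistance at each cable's middle compartment (MΩ)."""
    G = splu(_conductance_matrix(model))
    out = []
    for comp in model.cable_middle_compartments():
        rhs = np.zeros(model.n_compartments)
        rhs[comp] = 1.0
        out.append(
            {
                "cable": int(model.cable_index[comp]),
                "compartment": int(comp),
                "r_in_mohm": float(G.solve(rhs)[comp]),
            }
        )
    return pd.DataFrame(out)


def time_averaged_voltage(trace: VoltageTrace, window: tuple[float, float]) -> float:
    """Mean depolarization above rest over [t0, t1] (mV)."""
    t0, t1 = window
    mask = (trace.times >= t0) & (trace.times <= t1)
    if not mask.any():
        raise ValueError("window outside trace")
    return float((trace.values[mask] - trace.e_rest).mean())


def somatic_unit_kernels(
    model: CompartmentalModel,
    compartments,
    syn: SynapseParams,
    duration: float = 200.0,
    dt: float = 0.025,
    grid_stride: int = 4,
):
    """Somatic response to one synaptic event at each listed compartment.

    Returns (t_grid, V) with V of shape (n_compartments_listed, n_grid),
    in mV above rest, subsampled by ``grid_stride`` for compact storage.
    The kernels underpin the linear fast path of the classification tasks.
    """
    comps = np.asarray(compartments, dtype=int)
    t_grid = None
    out = []
    for c in comps:
        tr = simulate(model, [(int(c), 0.0)], syn, duration, dt)
        v = tr.values[::grid_stride] - tr.e_rest
        if t_grid is None:
            t_grid = tr.times[::grid_stride]
        out.append(v)
    return t_grid, np.vstack(out)
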