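"""Spike-count classification experiments on model projection neurons.

Two ideal-observer tasks probe how wiring variability limits what a PN's
membrane potential can report about receptor-neuron (ORN) spike counts:

* odor detection — the ipsilateral ORN population fires a fixed number of
  spikes (12 at baseline, the spontaneous count for a 200 ms window; 13–20
  for increasingly strong "odors") and a threshold classifier reads the PN's
  time-averaged somatic depolarization µ;
* odor lateralization — both antennae fire (one at baseline, the other
  driven), every PN receives both antennae's input, and the classifier reads
  the difference between the side-averaged µ of left and right PNs.

Spike trains are conditioned Poisson: exactly ``n_spikes`` uniform times in
the window, each spike assigned to a uniformly random ORN; trials violating a
4 ms per-ORN refractory interval are rejected and redrawn.

For speed the per-trial voltage is computed on a *linear fast path*: the
somatic response kernel of a single synaptic event is precomputed per
compartment with the full solver, and trial responses are superposed from
those kernels.  This is exact in the small-conductance limit and ignores the
(weak, ~10%) sublinearity of conductance summation; the full solver remains
available as the reference (``method='full'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .cablesim import (
    DEFAULT_GMAX_NS,
    EQUALIZED_GMAX_NS,
    SynapseParams,
    SynapseSite,
    somatic_unit_kernels,
)

__all__ = [
    "spontaneous_rate_per_orn",
    "baseline_spike_count",
    "generate_population_spikes",
    "generate_trials",
    "ThresholdClassifier",
    "train_threshold_classifier",
    "KernelBank",
    "TaskResult",
    "run_detection_task",
    "run_lateralization_task",
]


def spontaneous_rate_per_orn(population_rate_hz: float = 58.0, n_orns: float = 26.5) -> float:
    """Spontaneous firing rate per ORN from the population event rate (Hz)."""
    return population_rate_hz / n_orns


def baseline_spike_count(
    population_rate_hz: float = 58.0, window_ms: float = 200.0
) -> int:
    """Expected spontaneous population spike count in the window, rounded."""
    return int(round(population_rate_hz * window_ms / 1000.0))


def generate_population_spikes(
    n_spikes: int,
    n_orns: int,
    window: float = 200.0,
    refractory: float = 4.0,
    seed: int | np.random.Generator = 0,
):
    """One trial: exactly ``n_spikes`` spikes in [0, window] ms.

    Times are uniform; each spike is assigned to a uniformly random ORN.
    Trials in which any ORN fires twice within ``refractory`` ms are rejected
    and redrawn wholesale.  Returns (times, orn_indices).
    """
    t, o = generate_trials(1, n_spikes, n_orns, window, refractory, seed)
    return t[0], o[0]


def _violations(times: np.ndarray, orns: np.ndarray, refractory: float) -> np.ndarray:
    """Boolean per-trial flag: some ORN fired twice within the refractory gap."""
    T, n = times.shape
    bad = np.zeros(T, dtype=bool)
    if n < 2:
        return bad
    for t in range(T):
        idx = np.lexsort((times[t], orns[t]))
        ot, tt = orns[t][idx], times[t][idx]
        same = ot[1:] == ot[:-1]
        bad[t] = bool(np.any(same & (np.diff(tt) < refractory)))
    return bad


def generate_trials(
    n_trials: int,
    n_spikes: int,
    n_orns: int,
    window: float = 200.0,
    refractory: float = 4.0,
    seed: int | np.random.Generator = 0,
):
    """Vectorized trials: times (n_trials, n_spikes), orns (n_trials, n_spikes)."""
    if n_spikes < 0:
        raise ValueError("n_spikes must be >= 0")
    if n_spikes > n_orns * window / refractory:
        raise ValueError(
            f"{n_spikes} spikes cannot satisfy a {refractory} ms refractory "
            f"across {n_orns} ORNs in {window} ms"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = rng.uniform(0.0, window, size=(n_trials, n_spikes))
    orns = rng.integers(0, n_orns, size=(n_trials, n_spikes))
    bad = _violations(times, orns, refractory)
    guard = 0
    while bad.any():
        k = int(bad.sum())
        times[bad] = rng.uniform(0.0, window, size=(k, n_spikes))
        orns[bad] = rng.integers(0, n_orns, size=(k, n_spikes))
        bad[bad] = _violations(times[bad], orns[bad], refractory)
        guard += 1
        if guard > 10_000:
            raise RuntimeError("refractory rejection did not converge")
    return times, orns


@dataclass
class ThresholdClassifier:
    """Binary classifier on a scalar: label 1 iff orientation·(x − threshold) > 0."""

    threshold: float
    orientation: int
    train_accuracy: float = np.nan

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.orientation * (x - self.threshold) > 0).astype(int)

    def accuracy(self, x, labels) -> float:
        return float((self.predict(x) == np.asarray(labels)).mean())


def train_threshold_classifier(values, labels) -> ThresholdClassifier:
    """Pick the threshold minimizing training error on a scalar feature.

    Orientation comes from the class means; ties between equally good
    thresholds are broken toward the midpoint of the class means.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    m0, m1 = x[y == 0].mean(), x[y == 1].mean()
    orient = 1 if m1 >= m0 else -1
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    # candidate cuts between consecutive sorted values
    cum1 = np.concatenate([[0], np.cumsum(ys == 1)])
    cum0 = np.concatenate([[0], np.cumsum(ys == 0)])
    n0, n1 = cum0[-1], cum1[-1]
    # threshold after position i (i = 0..n): errors if class1 is "above"
    if orient == 1:
        errors = cum1 + (n0 - cum0)
    else:
        errors = cum0 + (n1 - cum1)
    best = errors.min()
    candidates = np.flatnonzero(errors == best)
    mid = (m0 + m1) / 2.0

    def cut_value(i: int) -> float:
        if i == 0:
            return xs[0] - 1e-9
        if i == len(xs):
            return xs[-1] + 1e-9
        return (xs[i - 1] + xs[i]) / 2.0

    thr = min((cut_value(i) for i in candidates), key=lambda v: abs(v - mid))
    clf = ThresholdClassifier(float(thr), orient)
    clf.train_accuracy = clf.accuracy(x, y)
    return clf


class KernelBank:
    """Precomputed somatic unit-response kernels for one PN.

    For every compartment that carries synapses, the somatic voltage response
    h_c(t) to a single synaptic event is simulated once; the running integral
    H_c(u) = ∫₀ᵘ h_c dt then gives each event's contribution to the
    time-averaged voltage µ over the stimulus window:  an event at onset t₀
    contributes H_c(window − t₀)/window.
    """

    def __init__(
        self,
        model,
        sites: list[SynapseSite],
        syn: SynapseParams,
        window: float = 200.0,
        dt: float = 0.025,
        grid_stride: int = 4,
    ):
        self.window = window
        self.syn = syn
        self.sites = list(sites)
        comps = sorted({s.compartment_index for s in self.sites})
        self._comp_row = {c: i for i, c in enumerate(comps)}
        t, v = somatic_unit_kernels(model, comps, syn, duration=window, dt=dt, grid_stride=grid_stride)
        self.t_grid = t
        self.dt_grid = float(t[1] - t[0])
        # H in mV·ms, one row per compartment
        self.H = cumulative_trapezoid(v, t, axis=1, initial=0.0)
        self.site_rows = np.array([self._comp_row[s.compartment_index] for s in self.sites])
        self.site_orns = np.array([s.orn_id for s in self.sites])

    def _interp(self, rows: np.ndarray, u: np.ndarray) -> np.ndarray:
        """H[rows](u) with linear interpolation on the uniform grid."""
        pos = np.clip(u / self.dt_grid, 0.0, self.H.shape[1] - 1 - 1e-9)
        i0 = pos.astype(int)
        frac = pos - i0
        return self.H[rows, i0] * (1.0 - frac) + self.H[rows, i0 + 1] * frac

    def orn_kernel_matrix(self, orn_ids: list[str], site_rows=None) -> np.ndarray:
        """Σ of site kernels per ORN: (n_orns, n_grid), for the real wiring."""
        rows = self.site_rows if site_rows is None else site_rows
        K = np.zeros((len(orn_ids), self.H.shape[1]))
        index = {o: i for i, o in enumerate(orn_ids)}
        for r, o in zip(rows, self.site_orns):
            if o in index:
                K[index[o]] += self.H[r]
        return K

    def mu_trials(self, K: np.ndarray, times: np.ndarray, orns: np.ndarray, g_scale: float = 1.0) -> np.ndarray:
        """µ (mV) for conditioned-Poisson trials given per-ORN kernels K."""
        u = self.window - times
        pos = np.clip(u / self.dt_grid, 0.0, K.shape[1] - 1 - 1e-9)
        i0 = pos.astype(int)
        frac = pos - i0
        vals = K[orns, i0] * (1.0 - frac) + K[orns, i0 + 1] * frac
        return g_scale * vals.sum(axis=1) / self.window

    def mu_trials_equalized(
        self,
        orn_ids: list[str],
        times: np.ndarray,
        orns: np.ndarray,
        rng: np.random.Generator,
        g_scale: float = 1.0,
        antenna_of_orn: np.ndarray | None = None,
        site_antenna: np.ndarray | None = None,
    ) -> np.ndarray:
        """µ with per-trial equalized synapse counts.

        Site locations are redrawn without replacement each trial so every
        axon gets floor(N/k) or floor(N/k)+1 of them.  With ``antenna_of_orn``
        and ``site_antenna`` the equalization is performed independently per
        antenna pool (preserving any ipsi/contra asymmetry in pool sizes).
        """
        n_orns = len(orn_ids)
        T = times.shape[0]
        mu = np.zeros(T)
        if antenna_of_orn is None:
            pools = [(np.arange(n_orns), np.arange(len(self.site_rows)))]
        else:
            pools = []
            for a in np.unique(site_antenna):
                pools.append(
                    (np.flatnonzero(antenna_of_orn == a), np.flatnonzero(site_antenna == a))
                )
        u = self.window - times
        for t in range(T):
            # per-pool equalized assignment: orn index per site
            orn_of_site = np.empty(len(self.site_rows), dtype=int)
            for orn_pool, site_pool in pools:
                k, n = len(orn_pool), len(site_pool)
                if n == 0:
                    continue
                if k > n:
                    raise ValueError("more axons than synapses in an equalization pool")
                base, rem = divmod(n, k)
                counts = np.full(k, base)
                counts[rng.choice(k, size=rem, replace=False)] += 1
                assign = np.repeat(orn_pool, counts)
                orn_of_site[site_pool[rng.permutation(n)]] = assign
            # sum each spike's contribution over the sites of its ORN
            for sp in range(times.shape[1]):
                mask = orn_of_site == orns[t, sp]
                if mask.any():
                    mu[t] += self._interp(self.site_rows[mask], np.full(mask.sum(), u[t, sp])).sum()
        return g_scale * mu / self.window


@dataclass
class TaskResult:
    task: str                # 'detection' | 'lateralization'
    pn_id: str               # PN id, or 'population' for lateralization
    condition: int           # odor spike count
    baseline: int
    wiring: str              # 'real' | 'equalized'
    accuracy: float
    n_train: int
    n_test: int
    seed: int
    stim_side: str | None = None


def run_detection_task(
    bundle,
    conditions=tuple(range(13, 21)),
    baseline: int = 12,
    wiring: str = "real",
    syn: SynapseParams | None = None,
    n_train: int = 2500,
    n_test: int = 2500,
    seed: int = 0,
    window: float = 200.0,
    refractory: float = 4.0,
    kernel_banks: dict | None = None,
) -> list[TaskResult]:
    """Odor-detection accuracy per PN and condition.

    Only ORNs ipsilateral to each PN are simulated.  For each condition the
    classifier is trained on ``n_train`` baseline + ``n_train`` odor trials
    and scored on equally many held-out trials.  Equalized wiring redraws the
    synapse-to-axon allocation independently on every trial and scales the
    synaptic conductance down to keep the mean unitary response fixed.
    """
    syn = syn or SynapseParams()
    if wiring not in ("real", "equalized"):
        raise ValueError("wiring must be 'real' or 'equalized'")
    g_scale = EQUALIZED_GMAX_NS / DEFAULT_GMAX_NS if wiring == "equalized" else 1.0
    table = bundle.table
    results: list[TaskResult] = []
    rng = np.random.default_rng(seed)
    for pn in table.counts.columns:
        side = table.pn_side[pn]
        ipsi_orns = [o for o in table.orns_on(side) if table.counts.loc[o, pn] > 0]
        sites = [s for s in bundle.sites[pn] if s.orn_id in set(ipsi_orns)]
        if not sites:
            raise ValueError(f"no ipsilateral site map for {pn}")
        bank = (kernel_banks or {}).get(pn) or KernelBank(
            bundle.models[pn], sites, syn, window=window
        )
        if kernel_banks is not None and pn not in kernel_banks:
            kernel_banks[pn] = bank
        K = bank.orn_kernel_matrix(ipsi_orns)
        n_orns = len(ipsi_orns)

        def mu_of(n_spikes: int, n_trials: int) -> np.ndarray:
            t, o = generate_trials(n_trials, n_spikes, n_orns, window, refractory, rng)
            if wiring == "real":
                return bank.mu_trials(K, t, o, g_scale)
            return bank.mu_trials_equalized(ipsi_orns, t, o, rng, g_scale)

        for cond in conditions:
            mu_train = np.concatenate([mu_of(baseline, n_train), mu_of(cond, n_train)])
            y_train = np.concatenate([np.zeros(n_train, int), np.ones(n_train, int)])
            clf = train_threshold_classifier(mu_train, y_train)
            mu_test = np.concatenate([mu_of(baseline, n_test), mu_of(cond, n_test)])
            y_test = np.concatenate([np.zeros(n_test, int), np.ones(n_test, int)])
            results.append(
                TaskResult(
                    task="detection",
                    pn_id=pn,
                    condition=int(cond),
                    baseline=baseline,
                    wiring=wiring,
                    accuracy=clf.accuracy(mu_test, y_test),
                    n_train=n_train,
                    n_test=n_test,
                    seed=seed,
                )
            )
    return results


def run_lateralization_task(
    bundle,
    conditions=tuple(range(13, 21)),
    baseline: int = 12,
    wiring: str = "real",
    syn: SynapseParams | None = None,
    n_train: int = 2500,
    n_test: int = 2500,
    seed: int = 0,
    window: float = 200.0,
    refractory: float = 4.0,
    stim_sides=("L", "R"),
    kernel_banks: dict | None = None,
) -> list[TaskResult]:
    """Odor-lateralization accuracy of the PN population.

    Every PN receives both antennae's spike trains through its own synapse
    map (ipsilateral connections carry more synapses, which is what makes the
    task possible).  The decision scalar is mean µ over left PNs minus mean µ
    over right PNs; one classifier per condition and stimulated side.
    Equalization is applied independently per PN-antenna pool, preserving the
    average ipsi/contra asymmetry.
    """
    syn = syn or SynapseParams()
    if wiring not in ("real", "equalized"):
        raise ValueError("wiring must be 'real' or 'equalized'")
    g_scale = EQUALIZED_GMAX_NS / DEFAULT_GMAX_NS if wiring == "equalized" else 1.0
    table = bundle.table
    pn_ids = list(table.counts.columns)
    left_pns = [p for p in pn_ids if table.pn_side[p] == "L"]
    right_pns = [p for p in pn_ids if table.pn_side[p] == "R"]
    if not left_pns or not right_pns:
        raise ValueError("lateralization needs PNs on both sides")

    orn_ids = list(table.counts.index)
    orn_index = {o: i for i, o in enumerate(orn_ids)}
    antenna_of_orn = np.array([0 if table.orn_side[o] == "L" else 1 for o in orn_ids])
    left_orns = np.flatnonzero(antenna_of_orn == 0)
    right_orns = np.flatnonzero(antenna_of_orn == 1)

    rng = np.random.default_rng(seed)
    banks: dict[str, KernelBank] = {}
    K_real: dict[str, np.ndarray] = {}
    site_meta: dict[str, tuple] = {}
    for pn in pn_ids:
        sites = bundle.sites[pn]
        bank = (kernel_banks or {}).get(pn) or KernelBank(bundle.models[pn], sites, syn, window=window)
        if kernel_banks is not None and pn not in kernel_banks:
            kernel_banks[pn] = bank
        banks[pn] = bank
        K_real[pn] = bank.orn_kernel_matrix(orn_ids)
        site_ant = np.array([antenna_of_orn[orn_index[s.orn_id]] for s in bank.sites])
        site_meta[pn] = (site_ant,)

    def decision_scalars(n_left: int, n_right: int, n_trials: int) -> np.ndarray:
        tL, oL = generate_trials(n_trials, n_left, len(left_orns), window, refractory, rng)
        tR, oR = generate_trials(n_trials, n_right, len(right_orns), window, refractory, rng)
        times = np.concatenate([tL, tR], axis=1)
        orns = np.concatenate([left_orns[oL], right_orns[oR]], axis=1)
        mus = {}
        for pn in pn_ids:
            bank = banks[pn]
            if wiring == "real":
                mus[pn] = bank.mu_trials(K_real[pn], times, orns, g_scale)
            else:
                mus[pn] = bank.mu_trials_equalized(
                    orn_ids, times, orns, rng, g_scale,
                    antenna_of_orn=antenna_of_orn, site_antenna=site_meta[pn][0],
                )
        mu_left = np.mean([mus[p] for p in left_pns], axis=0)
        mu_right = np.mean([mus[p] for p in right_pns], axis=0)
        return mu_left - mu_right

    results: list[TaskResult] = []
    for stim in stim_sides:
        for cond in conditions:
            nL, nR = (cond, baseline) if stim == "L" else (baseline, cond)
            x_tr = np.concatenate(
                [decision_scalars(baseline, baseline, n_train), decision_scalars(nL, nR, n_train)]
            )
            y_tr = np.concatenate([np.zeros(n_train, int), np.ones(n_train, int)])
            clf = train_threshold_classifier(x_tr, y_tr)
            x_te = np.concatenate(
                [decision_scalars(baseline, baseline, n_test), decision_scalars(nL, nR, n_test)]
            )
            y_te = np.concatenate([np.zeros(n_test, int), np.ones(n_test, int)])
            results.append(
                TaskResult(
                    task="lateralization",
                    pn_id="population",
                    condition=int(cond),
                    baseline=baseline,
                    wiring=wiring,
                    accuracy=clf.accuracy(x_te, y_te),
                    n_train=n_train,
                    n_test=n_test,
                    seed=seed,
                    stim_side=stim,
                )
            )
    return results
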