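"""Synthetic circuits, morphologies and synapse tables.

These generators stand in for an electron-microscopy reconstruction of a
bilateral olfactory glomerulus: a population of receptor-neuron (ORN) axons,
most projecting to both sides of the brain, converging onto a handful of
projection neurons (PNs) per side.  The statistical structure matches what
such reconstructions report — 27/26 ORNs per antenna with one unilateral axon
per side, 3 left + 2 right PNs, ~35% more synapses per ipsilateral connection,
a coefficient of variation of ~0.31 in each ORN's normalized contribution,
shared per-ORN strength factors within a brain side (but not across sides),
and synapse placement that is uniform per unit dendritic path length.

Count model: for ORN i (home side s) and PN j (side t),

    count_ij = max(1, round(base · r^[s=t] · exp(f_i^t) · d_j · ε_ij))

with r the ipsi/contra ratio, f_i^t a per-ORN latent log-strength drawn
independently for each *target side* t (this is the minimal mechanism giving
within-side-only correlations between PNs), d_j a per-PN dendrite-size
factor, and ε_ij i.i.d. lognormal noise.  base is calibrated so the expected
ipsilateral mean equals ``mean_syn_ipsi``; the ε variance is calibrated so the
total CV of normalized contributions equals ``connection_cv``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cablesim import MembraneParams, SynapseSite
from .connectivity import ConnectivityTable
from .morphology import (
    SWC_DENDRITE,
    SWC_NEURITE,
    SWC_SOMA,
    CompartmentalModel,
    Morphology,
    build_compartmental_model,
    total_path_length,
)

__all__ = [
    "CircuitSpec",
    "MorphologySpec",
    "generate_morphology",
    "generate_circuit",
    "place_synapses",
    "generate_synapse_sizes",
    "CircuitBundle",
    "make_bundle",
]

_MIN_TIP_RADIUS = 0.05  # µm; a branch thinner than this cannot grow further


@dataclass(frozen=True)
class CircuitSpec:
    """Parameters of the synthetic ORN→PN circuit (defaults: DM6-like)."""

    n_orns_left: int = 27
    n_orns_right: int = 26
    n_pns_left: int = 3
    n_pns_right: int = 2
    mean_syn_ipsi: float = 26.4        # synapses per ipsilateral connection
    ipsi_contra_ratio: float = 1.35
    connection_cv: float = 0.31        # CV of normalized contributions
    side_factor_sd: float = 0.22       # SD of per-ORN per-side latent log-strength
    unilateral_orns_per_side: int = 1
    pn_size_factors: tuple | None = None  # None → per-side pool-share factors
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_orns_left, self.n_orns_right, self.n_pns_left, self.n_pns_right)
        if min(counts) < 1:
            raise ValueError("all neuron counts must be >= 1")
        if self.unilateral_orns_per_side < 0:
            raise ValueError("unilateral_orns_per_side must be >= 0")
        if self.ipsi_contra_ratio < 1:
            raise ValueError("ipsi_contra_ratio must be >= 1")
        if self.connection_cv < 0 or self.side_factor_sd < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if self.mean_syn_ipsi <= 0:
            raise ValueError("mean_syn_ipsi must be positive")


@dataclass(frozen=True)
class MorphologySpec:
    """Parameters of the synthetic dendritic tree.

    A soma, one primary neurite, then binary branching with exponential
    inter-branchpoint lengths (rate ``branch_rate`` per µm) and a fixed
    radius taper at every branch point.  Defaults give a tree whose passive
    load yields unitary EPSPs of roughly 5 mV with the default synapse model.
    """

    target_path_length: float = 2000.0   # µm, total path length of all segments
    branch_rate: float = 0.02            # branch points per µm
    radius_root: float = 0.5             # µm, dendrite radius at the primary fork
    radius_taper: float = 0.88           # child/parent radius ratio at branch points
    soma_radius: float = 4.0             # µm
    primary_neurite_length: float = 30.0 # µm, soma → dendrite tuft
    primary_neurite_radius: float = 1.0  # µm
    step: float = 5.0                    # µm, node spacing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_path_length <= 0:
            raise ValueError("target_path_length must be positive")
        if min(self.radius_root, self.soma_radius, self.primary_neurite_radius) <= 0:
            raise ValueError("radii must be positive")
        if self.branch_rate < 0:
            raise ValueError("branch_rate must be >= 0")
        if not 0 < self.radius_taper <= 1:
            raise ValueError("radius_taper must be in (0, 1]")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_morphology(spec: MorphologySpec) -> Morphology:
    """Grow a branched dendritic tree of the requested total path length.

    Deterministic given the spec's seed.  Total path length lands within 5%
    of target (the last step is trimmed to hit it exactly); radii are
    constant along a branch and shrink by ``radius_taper`` at each branch
    point, so they are non-increasing from root to tip.  Raises if every tip
    tapers below the minimum caliber before the target length is reached.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [1]
    parents = [-1]
    xyz = [np.zeros(3)]
    radius = [spec.soma_radius]
    labels = [SWC_SOMA]

    def add_node(parent_idx: int, pos: np.ndarray, r: float, label: int) -> int:
        ids.append(len(ids) + 1)
        parents.append(parent_idx)
        xyz.append(pos)
        radius.append(r)
        labels.append(label)
        return len(ids) - 1

    total = 0.0
    # primary neurite: straight, along +z
    n_prim = max(1, int(round(spec.primary_neurite_length / spec.step)))
    prev = 0
    for k in range(1, n_prim + 1):
        pos = np.array([0.0, 0.0, k * spec.primary_neurite_length / n_prim])
        prev = add_node(prev, pos, spec.primary_neurite_radius, SWC_NEURITE)
        total += spec.primary_neurite_length / n_prim

    def draw_branch_dist() -> float:
        if spec.branch_rate == 0:
            return math.inf
        return float(rng.exponential(1.0 / spec.branch_rate))

    # active tips: (node index, direction, radius, distance until next branch)
    d0 = _unit(np.array([0.0, 0.0, 1.0]))
    tips = [[prev, d0, spec.radius_root, draw_branch_dist()]]
    target = spec.target_path_length
    while total < target:
        if not tips:
            raise RuntimeError(
                "target path length unreachable: all branches tapered below "
                f"{_MIN_TIP_RADIUS} µm (grew {total:.0f} of {target:.0f} µm); "
                "reduce branch_rate or increase radius_root/radius_taper"
            )
        i = int(rng.integers(len(tips)))
        node, direction, r, dist = tips[i]
        step = min(spec.step, target - total, dist if dist > 0 else spec.step)
        direction = _unit(direction + 0.25 * rng.standard_normal(3))
        pos = xyz[node] + step * direction
        node = add_node(node, pos, r, SWC_DENDRITE)
        total += step
        dist -= step
        if dist <= 0 and total < target:
            # branch: two children with tapered radius, splayed directions
            new_r = r * spec.radius_taper
            tips.pop(i)
            if new_r >= _MIN_TIP_RADIUS:
                for _ in range(2):
                    d = _unit(direction + 0.8 * rng.standard_normal(3))
                    tips.append([node, d, new_r, draw_branch_dist()])
        else:
            tips[i] = [node, direction, r, dist]

    return Morphology(
        ids=np.array(ids),
        parents=np.array(parents),
        xyz=np.array(xyz),
        radius=np.array(radius),
        labels=np.array(labels),
    )


def _circuit_layout(spec: CircuitSpec):
    orn_ids = [f"ORN_L{i + 1:02d}" for i in range(spec.n_orns_left)] + [
        f"ORN_R{i + 1:02d}" for i in range(spec.n_orns_right)
    ]
    orn_side = ["L"] * spec.n_orns_left + ["R"] * spec.n_orns_right
    # the last ORN(s) of each side stay unilateral
    bilateral = np.ones(len(orn_ids), dtype=bool)
    for s, n_side in (("L", spec.n_orns_left), ("R", spec.n_orns_right)):
        k = min(spec.unilateral_orns_per_side, n_side)
        if s == "L":
            bilateral[spec.n_orns_left - k : spec.n_orns_left] = False
        else:
            bilateral[len(orn_ids) - k :] = False
    pn_ids = [f"PN_L{j + 1}" for j in range(spec.n_pns_left)] + [
        f"PN_R{j + 1}" for j in range(spec.n_pns_right)
    ]
    pn_side = ["L"] * spec.n_pns_left + ["R"] * spec.n_pns_right
    return orn_ids, np.array(orn_side), bilateral, pn_ids, np.array(pn_side)


def pn_size_factors(spec: CircuitSpec) -> np.ndarray:
    """Per-PN dendrite-size factors d_j.

    Default (None): per-side pool-share factors, mean(PNs per side) divided by
    the number of PNs on that PN's side — the sides then receive similar total
    synapse pools, so individual PNs on the side with fewer cells receive
    proportionally more (and are grown with correspondingly larger dendrites
    by :func:`make_bundle`).
    """
    if spec.pn_size_factors is not None:
        d = np.asarray(spec.pn_size_factors, dtype=float)
        if len(d) != spec.n_pns_left + spec.n_pns_right or (d <= 0).any():
            raise ValueError("pn_size_factors must be positive, one per PN")
        return d
    mean_n = (spec.n_pns_left + spec.n_pns_right) / 2.0
    return np.array(
        [mean_n / spec.n_pns_left] * spec.n_pns_left
        + [mean_n / spec.n_pns_right] * spec.n_pns_right
    )


def generate_circuit(spec: CircuitSpec) -> ConnectivityTable:
    """Draw a synapse-count matrix with the spec's statistical structure."""
    rng = np.random.default_rng(spec.seed)
    orn_ids, orn_side, bilateral, pn_ids, pn_side = _circuit_layout(spec)
    n_o, n_p = len(orn_ids), len(pn_ids)
    d = pn_size_factors(spec)

    sigma_tot2 = math.log1p(spec.connection_cv**2)
    sigma_f = spec.side_factor_sd
    if sigma_f**2 > sigma_tot2 + 1e-12:
        raise ValueError(
            f"connection_cv={spec.connection_cv} is infeasible: the per-side latent "
            f"factor (sd={sigma_f}) alone already implies a larger CV"
        )
    sigma_eps = math.sqrt(max(0.0, sigma_tot2 - sigma_f**2))

    # latent per-ORN factor per *target side*, lognormal with mean 1
    f = np.exp(rng.normal(-sigma_f**2 / 2.0, sigma_f, size=(n_o, 2)))
    eps = np.exp(rng.normal(-sigma_eps**2 / 2.0, sigma_eps, size=(n_o, n_p)))

    allowed = np.ones((n_o, n_p), dtype=bool)
    ipsi = orn_side[:, None] == pn_side[None, :]
    allowed[~bilateral[:, None] & ~ipsi] = False

    # calibrate base so E[count | ipsi pair] = mean_syn_ipsi
    d_ipsi_mean = np.broadcast_to(d, (n_o, n_p))[allowed & ipsi].mean()
    base = spec.mean_syn_ipsi / (spec.ipsi_contra_ratio * d_ipsi_mean)

    side_col = (pn_side == "R").astype(int)
    mu = base * np.where(ipsi, spec.ipsi_contra_ratio, 1.0) * f[:, side_col] * d[None, :] * eps
    counts = np.where(allowed, np.maximum(1, np.round(mu)).astype(int), 0)

    table = pd.DataFrame(counts, index=orn_ids, columns=pn_ids)
    return ConnectivityTable(
        table,
        pd.Series(orn_side, index=orn_ids),
        pd.Series(pn_side, index=pn_ids),
        pd.Series(bilateral, index=orn_ids),
    )


def place_synapses(
    model: CompartmentalModel,
    table: ConnectivityTable,
    pn_id: str,
    seed: int = 0,
) -> list[SynapseSite]:
    """Place each connected ORN's synapses uniformly per unit dendrite length.

    Positions are drawn independently across ORNs on the PN's dendritic
    cables (soma and primary neurite excluded) and bound to the compartment
    containing them.
    """
    if pn_id not in table.counts.columns:
        raise KeyError(f"{pn_id!r} not in connectivity table")
    rng = np.random.default_rng(seed)
    dend = [c for c in model.cables if c.label == SWC_DENDRITE]
    if not dend:
        dend = list(model.cables)  # unlabelled morphologies: use everything
    if not dend:
        raise ValueError("morphology has no cables to place synapses on")
    lengths = np.array([c.length for c in dend])
    cum = np.cumsum(lengths)
    total = cum[-1]

    sites: list[SynapseSite] = []
    sid = 0
    for orn in table.counts.index:
        n = int(table.counts.loc[orn, pn_id])
        if n == 0:
            continue
        pos = rng.uniform(0.0, total, size=n)
        for x in pos:
            k = int(np.searchsorted(cum, x, side="right"))
            k = min(k, len(dend) - 1)
            offset = x - (cum[k - 1] if k > 0 else 0.0)
            cable = dend[k]
            sites.append(
                SynapseSite(
                    orn_id=orn,
                    pn_id=pn_id,
                    compartment_index=model.locate(cable.index, offset),
                    site_id=sid,
                    cable_index=cable.index,
                    offset=float(offset),
                )
            )
            sid += 1
    return sites


def generate_synapse_sizes(
    n_connections: int,
    syn_per_connection: int,
    seed: int = 0,
    cv: float = 0.5,
    rho: float = 0.5,
    mean_tbar_volume_nm3: float = 5.0e7,
    mean_contact_area_nm2: float = 4.0e5,
    mean_polyady: float = 5.0,
) -> pd.DataFrame:
    """Per-synapse T-bar volumes and postsynaptic contact areas.

    Volume and area are drawn from a correlated bivariate lognormal with
    per-synapse coefficient of variation ``cv`` and log-scale correlation
    ``rho``; sizes are independent of the synapse count per connection.
    """
    if n_connections < 1 or syn_per_connection < 1:
        raise ValueError("need at least one connection and one synapse")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if not -1 <= rho <= 1:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    n = n_connections * syn_per_connection
    sigma2 = math.log1p(cv**2)
    sigma = math.sqrt(sigma2)
    if sigma == 0:
        vol = np.full(n, mean_tbar_volume_nm3)
        area = np.full(n, mean_contact_area_nm2)
    else:
        cov = sigma2 * np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([-sigma2 / 2.0] * 2, cov, size=n)
        vol = mean_tbar_volume_nm3 * np.exp(z[:, 0])
        area = mean_contact_area_nm2 * np.exp(z[:, 1])
    return pd.DataFrame(
        {
            "connection_id": np.repeat(np.arange(n_connections), syn_per_connection),
            "synapse_id": np.arange(n),
            "tbar_volume_nm3": vol,
            "contact_area_nm2": area,
            "n_postsynaptic_profiles": 1 + rng.poisson(mean_polyady - 1.0, size=n),
        }
    )


@dataclass
class CircuitBundle:
    """A complete synthetic preparation: wiring, PN models and synapse maps."""

    spec: CircuitSpec
    morph_spec: MorphologySpec
    table: ConnectivityTable
    morphologies: dict[str, Morphology]
    models: dict[str, CompartmentalModel]
    sites: dict[str, list[SynapseSite]]

    def path_lengths(self) -> dict[str, float]:
        return {pn: total_path_length(m) for pn, m in self.morphologies.items()}


def make_bundle(
    circuit_spec: CircuitSpec | None = None,
    morph_spec: MorphologySpec | None = None,
    membrane: MembraneParams | None = None,
    seed: int = 0,
    elec_upper: float = 0.1,
) -> CircuitBundle:
    """Generate a circuit plus one compartmental PN model per column.

    Each PN's dendrite target path length is scaled by its pool-share factor,
    mirroring the covariation of dendrite size with the per-cell synapse load
    (the side with fewer PNs has larger cells).  Sub-seeds are derived from
    ``seed`` deterministically.
    """
    circuit_spec = circuit_spec or CircuitSpec()
    morph_spec = morph_spec or MorphologySpec()
    membrane = membrane or MembraneParams()
    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(1 + 2 * (circuit_spec.n_pns_left + circuit_spec.n_pns_right))
    next_seed = iter(sub)

    cs = CircuitSpec(**{**circuit_spec.__dict__, "seed": int(next(next_seed).generate_state(1)[0] % 2**31)})
    table = generate_circuit(cs)
    d = pn_size_factors(circuit_spec)

    morphologies: dict[str, Morphology] = {}
    models: dict[str, CompartmentalModel] = {}
    sites: dict[str, list[SynapseSite]] = {}
    for j, pn in enumerate(table.counts.columns):
        mseed = int(next(next_seed).generate_state(1)[0] % 2**31)
        ms = MorphologySpec(
            **{
                **morph_spec.__dict__,
                "target_path_length": morph_spec.target_path_length * float(d[j]),
                "seed": mseed,
            }
        )
        morph = generate_morphology(ms)
        model = build_compartmental_model(morph, membrane, elec_upper=elec_upper)
        pseed = int(next(next_seed).generate_state(1)[0] % 2**31)
        morphologies[pn] = morph
        models[pn] = model
        sites[pn] = place_synapses(model, table, pn, seed=pseed)
    return CircuitBundle(circuit_spec, morph_spec, table, morphologies, models, sites)
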