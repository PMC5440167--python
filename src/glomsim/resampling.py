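"""Monte-Carlo resampling: permutation tests, Holm correction, synapse shuffles.

Permutation tests are two-sided with the add-one correction
p = (1 + #{|null| ≥ |observed|}) / (1 + n_perm), so p is never zero and the
test is exact-in-expectation under exchangeability.  The synapse-location
shuffle and synapse-count equalization reproduce the structural controls used
to separate "where synapses sit" from "how many synapses each axon gets":
shuffling permutes the pooled locations while keeping each axon's count;
equalization keeps the pooled locations and forces counts to be as equal as
possible (floor/ceil split, remainders assigned at random).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from statsmodels.stats.multitest import multipletests

from .cablesim import SynapseSite

__all__ = [
    "PermutationResult",
    "permutation_test_mean_diff",
    "permutation_test_correlation",
    "holm_correction",
    "shuffle_synapse_locations",
    "equalize_synapse_counts",
]


@dataclass
class PermutationResult:
    statistic_observed: float
    null_samples: np.ndarray
    p_value: float
    n_permutations: int
    seed: int

    def to_record(self) -> dict:
        return {
            "statistic": self.statistic_observed,
            "p": self.p_value,
            "n_perm": self.n_permutations,
            "seed": self.seed,
        }


def _addone_p(obs: float, null: np.ndarray) -> float:
    return float((1 + np.sum(np.abs(null) >= abs(obs))) / (1 + len(null)))


def permutation_test_mean_diff(x, y, n_perm: int = 10_000, seed: int = 0) -> PermutationResult:
    """Two-sided permutation test on the difference of means.

    Pools x and y, re-splits at the original sizes and recomputes
    mean(x*) − mean(y*) for each permutation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse", stacklevel=2)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    nx, ny = len(x), len(y)
    obs = x.mean() - y.mean()
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    null = perms[:, :nx].mean(axis=1) - perms[:, nx:].mean(axis=1)
    return PermutationResult(float(obs), null, _addone_p(obs, null), n_perm, seed)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def permutation_test_correlation(x, y, n_perm: int = 10_000, seed: int = 0) -> PermutationResult:
    """Two-sided permutation test on Pearson's r (null: permute y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of at least 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse", stacklevel=2)
    rng = np.random.default_rng(seed)
    obs = _pearson(x, y)
    yp = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    xc = (x - x.mean()) / (np.std(x) * len(x))
    yc = (yp - yp.mean(axis=1, keepdims=True)) / np.std(yp, axis=1, keepdims=True)
    null = yc @ xc
    return PermutationResult(obs, null, _addone_p(obs, null), n_perm, seed)


def holm_correction(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def _locations(sites: list[SynapseSite]) -> list[tuple]:
    return [(s.compartment_index, s.cable_index, s.offset) for s in sites]


def _rebind(site: SynapseSite, loc: tuple) -> SynapseSite:
    return _dc_replace(site, compartment_index=loc[0], cable_index=loc[1], offset=loc[2])


def shuffle_synapse_locations(sites: list[SynapseSite], seed: int = 0) -> list[SynapseSite]:
    """Permute the pooled synapse locations across all of a PN's sites.

    Each ORN keeps its synapse count; the multiset of locations is preserved
    exactly.  Used (typically with many repeats) to ask whether per-connection
    mean mEPSP amplitude and summation efficacy depend on where each axon's
    synapses actually sit.
    """
    rng = np.random.default_rng(seed)
    locs = _locations(sites)
    perm = rng.permutation(len(locs))
    return [_rebind(s, locs[perm[i]]) for i, s in enumerate(sites)]


def equalize_synapse_counts(sites: list[SynapseSite], seed: int = 0) -> list[SynapseSite]:
    """Reassign a pool of synapse locations so per-axon counts are near-equal.

    The N locations are drawn without replacement from the pool; each of the
    k axons receives floor(N/k) or floor(N/k)+1 sites (remainders assigned to
    randomly chosen axons).  Independent redraws (fresh seeds) give the
    trial-by-trial re-allocation used in the equalized-wiring experiments.
    """
    rng = np.random.default_rng(seed)
    orns = sorted({s.orn_id for s in sites})
    n, k = len(sites), len(orns)
    if k > n:
        raise ValueError(f"{k} axons but only {n} synapses to allocate")
    base, rem = divmod(n, k)
    counts = np.full(k, base)
    counts[rng.choice(k, size=rem, replace=False)] += 1
    locs = _locations(sites)
    perm = rng.permutation(n)
    out: list[SynapseSite] = []
    pn_id = sites[0].pn_id
    pos = 0
    for orn, cnt in zip(orns, counts):
        for _ in range(cnt):
            loc = locs[perm[pos]]
            out.append(
                SynapseSite(
                    orn_id=orn,
                    pn_id=pn_id,
                    compartment_index=loc[0],
                    site_id=pos,
                    cable_index=loc[1],
                    offset=loc[2],
                )
            )
            pos += 1
    return out
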