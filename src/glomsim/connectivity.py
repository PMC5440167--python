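"""Receptor-neuron → projection-neuron connectivity and synapse-size statistics.

The central object is the ORN×PN synapse-count matrix with left/right side
labels.  A *connection* is a cell with a positive count; "ipsilateral" is
always defined relative to the ORN soma's antenna.  All of the wiring
statistics reported by the pipeline — synapses per connection, normalized
contributions and their coefficient of variation, ipsi/contra surplus,
left/right per-cell totals, and cross-PN weight correlations — live here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import resampling

__all__ = [
    "ConnectivityTable",
    "load_connectivity",
    "save_connectivity",
    "connection_stats",
    "normalized_contributions",
    "contribution_cv",
    "ipsi_contra_comparison",
    "left_right_totals",
    "cross_pn_weight_correlations",
    "synapse_size_stats",
]


@dataclass
class ConnectivityTable:
    """ORN×PN synapse-count matrix with side labels.

    counts: DataFrame (rows = ORNs, columns = PNs) of non-negative integers.
    orn_side / pn_side: 'L' or 'R' per id.  orn_bilateral: False for axons
    that stay on their home side (those must have zero contralateral counts).
    """

    counts: pd.DataFrame
    orn_side: pd.Series
    pn_side: pd.Series
    orn_bilateral: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        c = self.counts
        if (np.asarray(c.values) < 0).any():
            bad = np.argwhere(c.values < 0)[0]
            raise ValueError(f"negative count at ({c.index[bad[0]]}, {c.columns[bad[1]]})")
        if not np.allclose(c.values, np.round(c.values)):
            bad = np.argwhere(~np.isclose(c.values, np.round(c.values)))[0]
            raise ValueError(f"non-integer count at ({c.index[bad[0]]}, {c.columns[bad[1]]})")
        self.counts = c.astype(int)
        self.orn_side = pd.Series(self.orn_side, index=c.index) if not isinstance(self.orn_side, pd.Series) else self.orn_side.reindex(c.index)
        self.pn_side = pd.Series(self.pn_side, index=c.columns) if not isinstance(self.pn_side, pd.Series) else self.pn_side.reindex(c.columns)
        if self.orn_bilateral is None:
            # infer: an ORN is bilateral if it touches a PN on the other side
            bil = []
            for orn in c.index:
                contra = [p for p in c.columns if self.pn_side[p] != self.orn_side[orn]]
                bil.append(bool(c.loc[orn, contra].sum() > 0) if contra else False)
            self.orn_bilateral = pd.Series(bil, index=c.index)
        for orn in c.index:
            if not self.orn_bilateral[orn]:
                contra = [p for p in c.columns if self.pn_side[p] != self.orn_side[orn]]
                if c.loc[orn, contra].sum() > 0:
                    raise ValueError(f"unilateral ORN {orn} has contralateral synapses")

    @property
    def n_orns(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pns(self) -> int:
        return self.counts.shape[1]

    def ipsi_mask(self) -> pd.DataFrame:
        """Boolean ORN×PN frame: ORN home side equals PN side."""
        return pd.DataFrame(
            self.orn_side.values[:, None] == self.pn_side.values[None, :],
            index=self.counts.index,
            columns=self.counts.columns,
        )

    def orns_on(self, side: str) -> pd.Index:
        return self.counts.index[self.orn_side.values == side]

    def pns_on(self, side: str) -> pd.Index:
        return self.counts.columns[self.pn_side.values == side]


def _side_of(name: str) -> str:
    m = re.search(r"(?:^|_)([LR])", name.upper())
    if m is None:
        raise ValueError(f"cannot parse side (L/R) from id {name!r}")
    return m.group(1)


def load_connectivity(path) -> ConnectivityTable:
    """Read the matrix CSV: rows = ORNs sorted by side, columns = PNs.

    Side labels are parsed from the row/column names (ids contain 'L' or 'R',
    e.g. 'ORN_L01', 'PN_R2'), matching the layout written by
    :func:`save_connectivity`.
    """
    df = pd.read_csv(path, index_col=0)
    vals = df.values
    bad = np.argwhere(~(np.isfinite(vals.astype(float)) & (vals.astype(float) >= 0)))
    if len(bad):
        i, j = bad[0]
        raise ValueError(f"invalid cell at ({df.index[i]}, {df.columns[j]}): {vals[i, j]}")
    orn_side = pd.Series([_side_of(str(i)) for i in df.index], index=df.index)
    pn_side = pd.Series([_side_of(str(c)) for c in df.columns], index=df.columns)
    return ConnectivityTable(df, orn_side, pn_side)


def save_connectivity(table: ConnectivityTable, path) -> None:
    """Write the matrix CSV (ORN rows sorted by side, PN columns sorted by side)."""
    order_r = sorted(table.counts.index, key=lambda i: (table.orn_side[i], str(i)))
    order_c = sorted(table.counts.columns, key=lambda c: (table.pn_side[c], str(c)))
    table.counts.loc[order_r, order_c].to_csv(path)


def connection_stats(table: ConnectivityTable) -> dict:
    """Connection counts and synapses-per-connection summaries.

    A connection is a cell with count > 0; the mean/median are over those
    cells.  Per-type breakdown crosses ORN side × PN side.
    """
    c = table.counts.values.astype(float)
    nz = c > 0
    per_type = []
    ipsi = table.ipsi_mask().values
    for orn_s in ("L", "R"):
        for pn_s in ("L", "R"):
            m = nz & (table.orn_side.values[:, None] == orn_s) & (table.pn_side.values[None, :] == pn_s)
            if m.any():
                per_type.append(
                    {
                        "orn_side": orn_s,
                        "pn_side": pn_s,
                        "kind": "ipsi" if orn_s == pn_s else "contra",
                        "n_connections": int(m.sum()),
                        "mean_synapses": float(c[m].mean()),
                    }
                )
    return {
        "n_connections": int(nz.sum()),
        "total_synapses": int(c.sum()),
        "mean_synapses_per_connection": float(c[nz].mean()),
        "median_synapses_per_connection": float(np.median(c[nz])),
        "n_ipsi_connections": int((nz & ipsi).sum()),
        "n_contra_connections": int((nz & ~ipsi).sum()),
        "by_type": pd.DataFrame(per_type),
    }


def normalized_contributions(table: ConnectivityTable, pool: str = "ipsilateral") -> pd.DataFrame:
    """Percentage contribution of each ORN to a PN's synapse pool.

    pool='ipsilateral': each PN's counts from its *ipsilateral* ORNs, divided
    by the summed ipsilateral counts, ×100 (contralateral cells are NaN).
    pool='per-antenna': normalization is done separately within each antenna,
    so every (antenna, PN) column sums to 100.
    """
    c = table.counts.astype(float)
    out = pd.DataFrame(np.nan, index=c.index, columns=c.columns)
    if pool == "ipsilateral":
        for pn in c.columns:
            orns = table.orns_on(table.pn_side[pn])
            tot = c.loc[orns, pn].sum()
            if tot == 0:
                raise ValueError(f"empty ipsilateral pool for {pn}")
            out.loc[orns, pn] = 100.0 * c.loc[orns, pn] / tot
    elif pool == "per-antenna":
        for pn in c.columns:
            for side in ("L", "R"):
                orns = table.orns_on(side)
                if len(orns) == 0:
                    continue
                tot = c.loc[orns, pn].sum()
                if tot == 0:
                    raise ValueError(f"empty {side}-antenna pool for {pn}")
                out.loc[orns, pn] = 100.0 * c.loc[orns, pn] / tot
    else:
        raise ValueError(f"unknown pool {pool!r}")
    return out


def contribution_cv(table: ConnectivityTable) -> float:
    """CV (sample SD / mean) of ipsilateral normalized contributions, pooled.

    Pools the percentage contributions across all PNs; only connected
    (count > 0) ipsilateral pairs enter, so unilateral axons' structural
    zeros on the far side do not dilute the estimate.
    """
    contrib = normalized_contributions(table, "ipsilateral")
    vals = contrib.values[(table.counts.values > 0) & table.ipsi_mask().values]
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise ValueError("need at least two ipsilateral connections")
    return float(np.std(vals, ddof=1) / np.mean(vals))


def ipsi_contra_comparison(table: ConnectivityTable) -> dict:
    """Per-PN ipsi vs contra mean synapses/connection and pooled surplus.

    The surplus 100·(ipsi/contra − 1) is reported both from grand means over
    connections and from the average of per-PN means; a paired t-test over
    PNs accompanies the per-PN comparison.
    """
    c = table.counts.values.astype(float)
    nz = c > 0
    ipsi = table.ipsi_mask().values
    per_pn = []
    for j, pn in enumerate(table.counts.columns):
        mi = nz[:, j] & ipsi[:, j]
        mc = nz[:, j] & ~ipsi[:, j]
        per_pn.append(
            {
                "pn": pn,
                "ipsi_mean": float(c[mi, j].mean()) if mi.any() else np.nan,
                "contra_mean": float(c[mc, j].mean()) if mc.any() else np.nan,
            }
        )
    per_pn = pd.DataFrame(per_pn)
    grand_i = float(c[nz & ipsi].mean())
    grand_c = float(c[nz & ~ipsi].mean())
    paired = per_pn.dropna()
    tt = sstats.ttest_rel(paired["ipsi_mean"], paired["contra_mean"]) if len(paired) >= 2 else None
    return {
        "per_pn": per_pn,
        "grand_mean_ipsi": grand_i,
        "grand_mean_contra": grand_c,
        "surplus_pct_grand": 100.0 * (grand_i / grand_c - 1.0),
        "surplus_pct_per_pn": 100.0 * (paired["ipsi_mean"] / paired["contra_mean"] - 1.0).mean(),
        "paired_t_p": float(tt.pvalue) if tt is not None else np.nan,
    }


def left_right_totals(table: ConnectivityTable, path_lengths: dict | None = None) -> dict:
    """Per-PN total afferent synapses, side means and percent difference.

    With ``path_lengths`` (µm per PN id) a per-µm synapse density is added.
    Percent difference is 100·(right mean / left mean − 1).
    """
    totals = table.counts.sum(axis=0).astype(float)
    left = totals[table.pns_on("L")]
    right = totals[table.pns_on("R")]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("both sides must have PNs")
    per_pn = pd.DataFrame({"total_synapses": totals, "side": table.pn_side})
    if path_lengths is not None:
        per_pn["path_length_um"] = pd.Series(path_lengths)
        per_pn["density_per_um"] = per_pn["total_synapses"] / per_pn["path_length_um"]
    return {
        "per_pn": per_pn,
        "left_mean": float(left.mean()),
        "right_mean": float(right.mean()),
        "right_vs_left_pct": 100.0 * (float(right.mean()) / float(left.mean()) - 1.0),
    }


def cross_pn_weight_correlations(
    table: ConnectivityTable,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlations of normalized contributions between PN pairs.

    Computed separately per antenna on the per-antenna percentages.  Rows
    carry the antenna, the PN pair, whether the pair is same-side, r and a
    permutation p-value; the same-side family additionally gets Holm-adjusted
    p-values (m = number of same-side tests).
    """
    contrib = normalized_contributions(table, "per-antenna")
    pns = list(table.counts.columns)
    rows = []
    rng_seed = seed
    for side in ("L", "R"):
        orns = table.orns_on(side)
        if len(orns) < 3:
            raise ValueError(f"need at least 3 ORNs per antenna, {side} has {len(orns)}")
        for a in range(len(pns)):
            for b in range(a + 1, len(pns)):
                x = contrib.loc[orns, pns[a]].values
                y = contrib.loc[orns, pns[b]].values
                if np.std(x) == 0 or np.std(y) == 0:
                    rows.append(
                        {"antenna": side, "pn_a": pns[a], "pn_b": pns[b],
                         "same_side": table.pn_side[pns[a]] == table.pn_side[pns[b]],
                         "r": np.nan, "p": np.nan, "degenerate": True}
                    )
                    continue
                res = resampling.permutation_test_correlation(x, y, n_perm=n_perm, seed=rng_seed)
                rng_seed += 1
                rows.append(
                    {"antenna": side, "pn_a": pns[a], "pn_b": pns[b],
                     "same_side": table.pn_side[pns[a]] == table.pn_side[pns[b]],
                     "r": res.statistic_observed, "p": res.p_value, "degenerate": False}
                )
    df = pd.DataFrame(rows)
    df["p_holm"] = np.nan
    same = df["same_side"] & ~df["degenerate"]
    if same.any():
        df.loc[same, "p_holm"] = resampling.holm_correction(df.loc[same, "p"].values)
    return df


def synapse_size_stats(geom: pd.DataFrame) -> dict:
    """Per-synapse and per-connection-mean size variability.

    ``geom`` needs columns connection_id, tbar_volume_nm3, contact_area_nm2
    and optionally synapse counts per connection (inferred by group size).
    Reports raw CVs, CVs of per-connection means (which shrink roughly as
    1/√n when synapses vary independently), the volume↔area correlation and
    the mean-size↔synapse-count correlation.
    """
    if geom["connection_id"].nunique() < 2:
        raise ValueError("need at least two connections")

    def cv(x):
        x = np.asarray(x, dtype=float)
        return float(np.std(x, ddof=1) / np.mean(x)) if np.mean(x) != 0 else 0.0

    g = geom.groupby("connection_id")
    means = g[["tbar_volume_nm3", "contact_area_nm2"]].mean()
    counts = g.size()
    def safe_pearson(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return np.nan, np.nan
        return sstats.pearsonr(a, b)

    r_va, p_va = safe_pearson(geom["tbar_volume_nm3"], geom["contact_area_nm2"])
    r_vc, p_vc = safe_pearson(means["tbar_volume_nm3"], counts)
    r_ac, p_ac = safe_pearson(means["contact_area_nm2"], counts)
    return {
        "cv_tbar_volume": cv(geom["tbar_volume_nm3"]),
        "cv_contact_area": cv(geom["contact_area_nm2"]),
        "cv_mean_tbar_volume": cv(means["tbar_volume_nm3"]),
        "cv_mean_contact_area": cv(means["contact_area_nm2"]),
        "r_volume_area": float(r_va),
        "p_volume_area": float(p_va),
        "r_mean_volume_count": float(r_vc),
        "p_mean_volume_count": float(p_vc),
        "r_mean_area_count": float(r_ac),
        "p_mean_area_count": float(p_ac),
        "mean_synapses_per_connection": float(counts.mean()),
    }
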