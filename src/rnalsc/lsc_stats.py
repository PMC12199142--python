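"""Local stability compensation (LSC) statistics over substructure databases.

The unit of analysis is one loop together with its adjacent stem energies.
The net free energy of a loop is

    net dG = loop dG + stem dG                     (hairpin: one stem)
    net dG = loop dG + (stem1 dG + stem2 dG) / 2   (bulge / internal loop)

in kcal/mol at 37 C.  Compensation shows up as a negative correlation
between loop dG and adjacent stem dG, and as a reduced variance of net dG
relative to a within-structure rotation control in which each loop is
re-paired with the stems of a distal loop of the same type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energies import ComponentEnergy
from .structures import RnaStructure, SubstructureSet

__all__ = [
    "SubstructureRecord",
    "BinnedSeries",
    "RegressionResult",
    "RotationControlResult",
    "make_records",
    "bin_aggregate_regress",
    "rotation_control",
    "variance_f_test",
    "density_estimate",
    "group_summary",
    "records_to_frame",
    "records_to_tsv",
    "read_records",
]

log = logging.getLogger(__name__)

_LOOP_KIND = {"H": "hairpin", "B": "bulge", "I": "internal"}


@dataclass
class SubstructureRecord:
    """One loop with its adjacent stem energies; the LSC unit of analysis."""

    structure_id: str
    loop_label: str
    loop_type: str  # hairpin | bulge | internal
    loop_dg: float
    stem_dgs: tuple[float, ...]  # 1 value (hairpin) or 2 (two-way junction)
    stem_labels: tuple[str, ...]
    family: str = ""
    taxon: str = ""
    loop_size: int = 0
    stem_lengths: tuple[int, ...] = ()

    @property
    def stem_dg(self) -> float:
        """Adjacent stem statistic: the mean of the flanking stem energies."""
        return float(np.mean(self.stem_dgs))

    @property
    def net_dg(self) -> float:
        return self.loop_dg + self.stem_dg


@dataclass
class BinnedSeries:
    """Left-closed, right-open bins labeled by their left edge."""

    bin_width: float
    left_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return self.left_edges + self.bin_width / 2.0


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass
class RotationControlResult:
    control_net_dgs: np.ndarray
    true_net_dgs: np.ndarray
    f_statistic: float
    p_value: float
    bin_left_edges: np.ndarray
    freq_diff: np.ndarray  # per-bin frequency, true minus control
    n_structures: int


def make_records(
    annotated: Iterable[tuple[RnaStructure, SubstructureSet, Sequence[ComponentEnergy]]],
    families: dict[str, str] | None = None,
    taxa: dict[str, str] | None = None,
) -> list[SubstructureRecord]:
    """Build one record per scorable loop from annotated structures.

    ``annotated`` yields (structure, decomposition, component energies)
    triples as produced by :func:`rnalsc.energies.annotate_structure_energies`.
    Loops whose own energy or any adjacent stem energy is unscorable are
    skipped; the skip count is logged.
    """
    families = families or {}
    taxa = taxa or {}
    records: list[SubstructureRecord] = []
    skipped = 0
    for structure, sset, energies in annotated:
        emap = {e.label: e for e in energies}
        for loop in sset.loops():
            stem_labels = sset.adjacency.get(loop.label)
            loop_e = emap.get(loop.label)
            if not stem_labels or loop_e is None:
                skipped += 1
                log.debug("%s/%s: missing adjacency or energy", structure.id, loop.label)
                continue
            stem_es = [emap.get(lbl) for lbl in stem_labels]
            if not loop_e.scorable or any(e is None or not e.scorable for e in stem_es):
                skipped += 1
                continue
            records.append(
                SubstructureRecord(
                    structure_id=structure.id,
                    loop_label=loop.label,
                    loop_type=_LOOP_KIND[loop.label[0]],
                    loop_dg=loop_e.dg,
                    stem_dgs=tuple(e.dg for e in stem_es),
                    stem_labels=tuple(stem_labels),
                    family=families.get(structure.id, ""),
                    taxon=taxa.get(structure.id, ""),
                    loop_size=len(loop.loop_positions),
                    stem_lengths=tuple(
                        len(sset.by_label(lbl).pairs) for lbl in stem_labels
                    ),
                )
            )
    if skipped:
        log.info("make_records: skipped %d unscorable loop(s)", skipped)
    return records


def _bin_index(x: np.ndarray, bin_width: float) -> np.ndarray:
    return np.floor(x / bin_width).astype(int)


def bin_aggregate_regress(
    records: Sequence[SubstructureRecord],
    bin_width: float = 0.25,
    aggregate: str = "median",
    min_bin_count: int = 10,
) -> tuple[BinnedSeries, RegressionResult]:
    """Bin records by loop dG and regress the per-bin stem-dG aggregate.

    ``aggregate`` is ``"median"`` or ``"quantile05"`` (the 5% quantile,
    linear-interpolation method).  Bins are left-closed with width
    ``bin_width`` kcal/mol; bins holding fewer than ``min_bin_count`` records
    are excluded from the ordinary-least-squares fit of aggregate versus bin
    center.
    """
    if aggregate not in ("median", "quantile05"):
        raise ValueError(f"unknown aggregate '{aggregate}'")
    loop = np.array([r.loop_dg for r in records])
    stem = np.array([r.stem_dg for r in records])
    if loop.size == 0:
        raise ValueError("no records to bin")
    idx = _bin_index(loop, bin_width)
    uniq = np.unique(idx)
    edges, values, counts = [], [], []
    q = 0.5 if aggregate == "median" else 0.05
    for u in uniq:
        sel = stem[idx == u]
        edges.append(u * bin_width)
        values.append(float(np.quantile(sel, q)))  # linear interpolation (type 7)
        counts.append(int(sel.size))
    series = BinnedSeries(
        bin_width=bin_width,
        left_edges=np.array(edges),
        values=np.array(values),
        counts=np.array(counts),
    )
    keep = series.counts >= min_bin_count
    if keep.sum() < 2:
        raise ValueError(
            f"need >= 2 bins with >= {min_bin_count} records, have {int(keep.sum())}"
        )
    fit = stats.linregress(series.centers[keep], series.values[keep])
    reg = RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=int(keep.sum()),
    )
    return series, reg


def _rotation_offset(loops: list[SubstructureRecord]) -> int:
    """Smallest adjacency-free cyclic shift starting from floor(k/2)."""
    k = len(loops)
    own = [set(r.stem_labels) for r in loops]
    for delta in range(k):
        offset = (k // 2 + delta) % k
        if offset == 0:
            continue
        if all(not (own[i] & own[(i + offset) % k]) for i in range(k)):
            return offset
    raise ValueError("no adjacency-free rotation exists")


def rotation_control(
    records: Sequence[SubstructureRecord],
    bin_width: float = 0.25,
    min_loops: int = 4,
) -> RotationControlResult:
    """Within-structure rotation null for the net-dG distribution.

    For every structure contributing at least ``min_loops`` loops of a type
    (the eligibility rule: strictly more than three), loops of that type are
    ordered 5'->3' and each receives the stem energies of the loop a fixed
    cyclic shift away (shift floor(k/2), incremented until no loop receives
    one of its own adjacent stems).  Control net dG uses the same averaging
    rule as the true statistic.  Reduced true-versus-control variance is the
    LSC signal, tested with a two-sided variance F-test.
    """
    groups: dict[tuple[str, str], list[SubstructureRecord]] = {}
    for r in records:
        groups.setdefault((r.structure_id, r.loop_type), []).append(r)
    true_net, control_net = [], []
    n_structures = 0
    for (sid, ltype), loops in sorted(groups.items()):
        if len(loops) < min_loops:
            continue
        loops = sorted(loops, key=lambda r: int(r.loop_label[1:]))
        k = len(loops)
        offset = _rotation_offset(loops)
        n_structures += 1
        for i, r in enumerate(loops):
            donor = loops[(i + offset) % k]
            true_net.append(r.net_dg)
            control_net.append(r.loop_dg + float(np.mean(donor.stem_dgs)))
    if not n_structures:
        raise ValueError(
            f"no structure contributes >= {min_loops} loops of one type"
        )
    true_net = np.array(true_net)
    control_net = np.array(control_net)
    f_stat, p = variance_f_test(true_net, control_net)
    lo = math.floor(min(true_net.min(), control_net.min()) / bin_width)
    hi = math.floor(max(true_net.max(), control_net.max()) / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    freq_true = np.histogram(true_net, bins=edges)[0] / true_net.size
    freq_ctrl = np.histogram(control_net, bins=edges)[0] / control_net.size
    return RotationControlResult(
        control_net_dgs=control_net,
        true_net_dgs=true_net,
        f_statistic=f_stat,
        p_value=p,
        bin_left_edges=edges[:-1],
        freq_diff=freq_true - freq_ctrl,
        n_structures=n_structures,
    )


def variance_f_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided F-test for equality of variances.

    F = var(x) / var(y) with unbiased (n-1) estimators, compared against the
    F distribution with (n_x - 1, n_y - 1) degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have size >= 2")
    vy = y.var(ddof=1)
    if vy == 0:
        raise ValueError("zero variance in denominator sample")
    f = x.var(ddof=1) / vy
    dist = stats.f(x.size - 1, y.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def density_estimate(
    net_dgs: Sequence[float], grid: Sequence[float]
) -> np.ndarray:
    """Gaussian kernel density of net dG values on a grid (Scott's rule)."""
    values = np.asarray(net_dgs, dtype=float)
    if values.size < 10:
        raise ValueError(f"need >= 10 values for a density estimate, have {values.size}")
    if values.var() == 0:
        raise ValueError("all values identical: zero-bandwidth density undefined")
    kde = stats.gaussian_kde(values, bw_method="scott")
    return kde(np.asarray(grid, dtype=float))


def group_summary(
    records: Sequence[SubstructureRecord],
    group_by: str = "family",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group net-dG summaries and pairwise Mann-Whitney U contrasts.

    Returns ``(summary, pairwise)``: the summary has one row per group with
    median (linear-interpolation quantile), sample SD (n-1 denominator), and
    n; groups with fewer than 2 records are excluded (and logged).  The
    pairwise table holds two-sided Mann-Whitney U tests for every group pair.
    """
    if group_by not in ("family", "taxon"):
        raise ValueError("group_by must be 'family' or 'taxon'")
    by: dict[str, list[float]] = {}
    for r in records:
        key = getattr(r, group_by)
        by.setdefault(key, []).append(r.net_dg)
    rows = []
    for key in sorted(by):
        vals = np.array(by[key])
        if vals.size < 2:
            log.info("group_summary: excluding group %r (n=%d)", key, vals.size)
            del by[key]
            continue
        rows.append(
            {
                group_by: key,
                "median_net_dg": float(np.median(vals)),
                "sd_net_dg": float(vals.std(ddof=1)),
                "n": int(vals.size),
            }
        )
    summary = pd.DataFrame(rows)
    pair_rows = []
    for a, b in combinations(sorted(by), 2):
        u, p = stats.mannwhitneyu(by[a], by[b], alternative="two-sided")
        pair_rows.append({"group_a": a, "group_b": b, "u_statistic": float(u), "p_value": float(p)})
    pairwise = pd.DataFrame(pair_rows)
    return summary, pairwise


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

_COLUMNS = [
    "structure_id", "loop_label", "loop_type", "loop_dg", "stem_dgs",
    "stem_labels", "net_dg", "family", "taxon", "loop_size", "stem_lengths",
]


def records_to_frame(records: Sequence[SubstructureRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "structure_id": r.structure_id,
                "loop_label": r.loop_label,
                "loop_type": r.loop_type,
                "loop_dg": r.loop_dg,
                "stem_dgs": ",".join(f"{v:.2f}" for v in r.stem_dgs),
                "stem_labels": ",".join(r.stem_labels),
                "net_dg": r.net_dg,
                "family": r.family,
                "taxon": r.taxon,
                "loop_size": r.loop_size,
                "stem_lengths": ",".join(str(v) for v in r.stem_lengths),
            }
            for r in records
        ],
        columns=_COLUMNS,
    )


def records_to_tsv(records: Sequence[SubstructureRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records(path) -> list[SubstructureRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SubstructureRecord(
                structure_id=str(row.structure_id),
                loop_label=str(row.loop_label),
                loop_type=str(row.loop_type),
                loop_dg=float(row.loop_dg),
                stem_dgs=tuple(float(v) for v in str(row.stem_dgs).split(",")),
                stem_labels=tuple(str(row.stem_labels).split(",")),
                family=str(row.family),
                taxon=str(row.taxon),
                loop_size=int(row.loop_size),
                stem_lengths=tuple(
                    int(v) for v in str(row.stem_lengths).split(",") if v
                ),
            )
        )
    return out
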