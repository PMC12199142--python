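"""Folding fidelity from DMS reactivity tables.

DMS methylates accessible A and C nucleotides; after mutational profiling,
per-position mutation fractions are high where the nucleotide is unpaired.
Fidelity of a designed structure is quantified as the AUROC separating
designed-unpaired (positives) from designed-paired (negatives) A/C
nucleotides by their reactivity, computed in three scopes: global (all
positions), local (the randomized variable region), and distal (its
complement, a control).

Downstream summaries: mean stem/loop reactivities per region, per-position
stem reactivity profiles by net-dG bin, and a Hill-equation fit of binned
local AUROC versus net stabilization whose AUROC = 0.9 crossing defines the
minimum local stability for consistent folding.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .library_design import DesignedConstruct
from .structures import parse_dotbracket

__all__ = [
    "ReactivityProfile",
    "FidelityRecord",
    "HillFit",
    "PositionalProfile",
    "filter_c_repeats",
    "auroc",
    "region_reactivity",
    "compute_fidelity",
    "per_position_profile",
    "fit_hill",
    "regress_fidelity",
    "read_reactivity_tsv",
    "write_reactivity_tsv",
]

log = logging.getLogger(__name__)

LOG_PSEUDOCOUNT = 1e-4
DEFAULT_NET_DG_BINS = (-20.0, -15.0, -10.0, -5.0, 0.0, 10.0)


@dataclass
class ReactivityProfile:
    """Per-position DMS mutation fractions with the designed structure."""

    construct_id: str
    sequence: str
    pair_table: list[int]  # 1-based designed pairing; 0 = unpaired
    reactivity: np.ndarray  # mutation fraction per position, >= 0
    depth: np.ndarray | None = None
    local_positions: frozenset[int] = frozenset()  # 1-based randomized region

    def __post_init__(self):
        n = len(self.sequence)
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        if self.reactivity.size != n or len(self.pair_table) != n + 1:
            raise ValueError(f"{self.construct_id}: vector lengths != sequence length")
        if (self.reactivity < 0).any():
            raise ValueError(f"{self.construct_id}: negative reactivity")

    def scope_mask(self, scope: str) -> np.ndarray:
        """Boolean mask (0-based) for a scope in {global, local, distal}."""
        n = len(self.sequence)
        if scope == "global":
            return np.ones(n, dtype=bool)
        local = np.zeros(n, dtype=bool)
        for p in self.local_positions:
            local[p - 1] = True
        if scope == "local":
            return local
        if scope == "distal":
            return ~local
        raise ValueError(f"unknown scope '{scope}'")

    @property
    def ac_mask(self) -> np.ndarray:
        return np.array([b in "AC" for b in self.sequence])

    @property
    def paired_mask(self) -> np.ndarray:
        return np.array([self.pair_table[i] != 0 for i in range(1, len(self.sequence) + 1)])


@dataclass
class FidelityRecord:
    """Per-construct fidelity metrics; None marks an undefined quantity."""

    construct_id: str
    net_dg: float
    auroc_global: float | None
    auroc_local: float | None
    auroc_distal: float | None
    stem_reactivity_local: float | None
    stem_reactivity_distal: float | None
    loop_reactivity_local: float | None
    loop_reactivity_distal: float | None


@dataclass
class HillFit:
    """Hill-equation fit of binned local AUROC vs stability s = s_offset - net dG."""

    a0: float  # baseline AUROC at zero stabilization
    hill: float  # Hill coefficient (> 0)
    s50: float  # midpoint on the stability axis, kcal/mol
    s_offset: float
    g09: float | None  # net dG where the fitted curve crosses AUROC 0.9
    rss: float
    n_bins: int
    bin_left_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_means: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, net_dg):
        s = np.maximum(self.s_offset - np.asarray(net_dg, dtype=float), 1e-12)
        return self.a0 + (1 - self.a0) * s**self.hill / (self.s50**self.hill + s**self.hill)

    def to_json(self, path) -> None:
        payload = {
            "a0": self.a0, "hill": self.hill, "s50": self.s50,
            "s_offset": self.s_offset, "g09": self.g09, "rss": self.rss,
            "n_bins": self.n_bins,
            "bin_left_edges": self.bin_left_edges.tolist(),
            "bin_means": self.bin_means.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class PositionalProfile:
    """Mean stem reactivity at pair positions counted outward from the loop."""

    bin_edges: tuple[float, ...]
    positions: list[int]  # 1 = closing pair
    means: np.ndarray  # (n_bins, n_positions), NaN where suppressed
    ci95: np.ndarray
    counts: np.ndarray  # contributing nucleotides per bin x position


def filter_c_repeats(
    profiles: Iterable[ReactivityProfile], max_run: int = 4
) -> tuple[list[ReactivityProfile], list[ReactivityProfile]]:
    """Split profiles into (kept, removed) by the C-repeat rule.

    Constructs containing a run of more than ``max_run`` consecutive C
    residues are removed: successive reactive nucleotides make mutation
    fractions unreliable there.
    """
    pattern = re.compile("C" * (max_run + 1))
    kept, removed = [], []
    for p in profiles:
        (removed if pattern.search(p.sequence) else kept).append(p)
    if removed:
        log.info("filter_c_repeats: removed %d construct(s)", len(removed))
    return kept, removed


def _rank_auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Midrank (tie-aware) probability that a positive outranks a negative."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auroc(profile: ReactivityProfile, scope: str = "global") -> float | None:
    """AUROC of reactivity vs designed pairing over A/C positions in a scope.

    Positives are designed-unpaired, negatives designed-paired; ties are
    handled by midranks.  Returns None (undefined) when the scope holds
    fewer than 2 positives or 2 negatives.
    """
    mask = profile.scope_mask(scope) & profile.ac_mask
    paired = profile.paired_mask
    pos = profile.reactivity[mask & ~paired]
    neg = profile.reactivity[mask & paired]
    if pos.size < 2 or neg.size < 2:
        return None
    return _rank_auroc(pos, neg)


def region_reactivity(
    profile: ReactivityProfile,
    target: tuple[str, str] = ("stem", "local"),
    log_transform: bool = False,
) -> float | None:
    """Mean A/C reactivity over (stem|loop) x (local|distal) positions.

    With ``log_transform`` the natural log of (mean + 1e-4) is returned.
    None when the target holds no A/C positions.
    """
    kind, region = target
    if kind not in ("stem", "loop"):
        raise ValueError("target kind must be 'stem' or 'loop'")
    mask = profile.scope_mask(region) & profile.ac_mask
    mask &= profile.paired_mask if kind == "stem" else ~profile.paired_mask
    if not mask.any():
        return None
    mean = float(profile.reactivity[mask].mean())
    return math.log(mean + LOG_PSEUDOCOUNT) if log_transform else mean


def compute_fidelity(
    profile: ReactivityProfile, net_dg: float
) -> FidelityRecord:
    """All per-construct fidelity metrics for one reactivity profile."""
    return FidelityRecord(
        construct_id=profile.construct_id,
        net_dg=net_dg,
        auroc_global=auroc(profile, "global"),
        auroc_local=auroc(profile, "local"),
        auroc_distal=auroc(profile, "distal"),
        stem_reactivity_local=region_reactivity(profile, ("stem", "local")),
        stem_reactivity_distal=region_reactivity(profile, ("stem", "distal")),
        loop_reactivity_local=region_reactivity(profile, ("loop", "local")),
        loop_reactivity_distal=region_reactivity(profile, ("loop", "distal")),
    )


def _adjacent_stem_pairs(construct: DesignedConstruct):
    """Base pairs of the variable loop's stem(s), ordered outward from the loop.

    Returns a list of per-stem pair lists; position k of the profile is the
    k-th pair of each stem counted away from the loop (1 = closing pair).
    """
    from .structures import decompose

    struct = construct.structure()
    sset = decompose(struct)
    loop_obj = sset.by_label(construct.loop_label)
    ordered = []
    for lbl in construct.stem_labels:
        stem = sset.by_label(lbl)
        if construct.loop_type == "hairpin":
            ordered.append(list(reversed(stem.pairs)))  # innermost pair closes the loop
        else:
            # outer stem: innermost pair faces the loop; inner stem: outermost
            if stem.pairs[-1] == loop_obj.outer_pair:
                ordered.append(list(reversed(stem.pairs)))
            else:
                ordered.append(list(stem.pairs))
    return ordered


def per_position_profile(
    items: Sequence[tuple[ReactivityProfile, DesignedConstruct]],
    bin_edges: Sequence[float] = DEFAULT_NET_DG_BINS,
    max_position: int = 6,
    min_nucleotides: int = 70,
) -> PositionalProfile:
    """Mean stem reactivity by pair position outward from the variable loop.

    Reactivities are averaged over the A/C nucleotides of each pair; for
    two-way junctions a position contributes only where both stems have a
    pair at that index, and the two stems' values are averaged.  Bins are
    net-dG intervals (left-closed); bins contributing fewer than
    ``min_nucleotides`` A/C nucleotides at a position are suppressed (NaN).
    """
    edges = np.asarray(bin_edges, dtype=float)
    n_bins = edges.size - 1
    sums = np.zeros((n_bins, max_position))
    sqsums = np.zeros((n_bins, max_position))
    n_constructs = np.zeros((n_bins, max_position))
    nt_counts = np.zeros((n_bins, max_position), dtype=int)
    for profile, construct in items:
        b = np.searchsorted(edges, construct.net_dg, side="right") - 1
        if b < 0 or b >= n_bins:
            continue
        stem_pairs = _adjacent_stem_pairs(construct)
        seq = profile.sequence
        react = profile.reactivity
        for k in range(max_position):
            vals, nts = [], 0
            for pairs in stem_pairs:
                if k >= len(pairs):
                    vals = []  # position must exist on every adjacent stem
                    break
                i, j = pairs[k]
                ac = [p for p in (i, j) if seq[p - 1] in "AC"]
                if not ac:
                    continue
                vals.append(float(np.mean([react[p - 1] for p in ac])))
                nts += len(ac)
            if vals:
                v = float(np.mean(vals))
                sums[b, k] += v
                sqsums[b, k] += v * v
                n_constructs[b, k] += 1
                nt_counts[b, k] += nts
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / n_constructs
        var = sqsums / n_constructs - means**2
        se = np.sqrt(np.maximum(var, 0) / np.maximum(n_constructs, 1))
    ci = 1.96 * se
    suppress = nt_counts < min_nucleotides
    means[suppress] = np.nan
    ci[suppress] = np.nan
    if np.isnan(means).all():
        log.warning("per_position_profile: no bin reaches %d nucleotides", min_nucleotides)
    return PositionalProfile(
        bin_edges=tuple(edges),
        positions=list(range(1, max_position + 1)),
        means=means,
        ci95=ci,
        counts=nt_counts,
    )


def _hill(s, a0, h, s50):
    return a0 + (1 - a0) * s**h / (s50**h + s**h)


def fit_hill(
    records: Sequence[FidelityRecord],
    bin_width: float = 0.2,
    s_offset: float = 10.0,
    min_bins: int = 6,
    min_span: float = 3.0,
    weight_bins: bool = True,
) -> HillFit:
    """Fit binned local AUROC vs net dG to a Hill saturation curve.

    Local AUROCs are averaged in net-dG bins of ``bin_width`` kcal/mol; the
    stability axis is s = s_offset - net dG, and the fitted curve is
    f(s) = A0 + (1 - A0) * s^h / (s50^h + s^h) with A0 in [0.3, 0.9],
    h in (0, 20], s50 in (0, 30] (bounded nonlinear least squares).  With
    ``weight_bins`` (default), bin means are weighted by the square root of
    their counts — a bin mean's sampling variance scales as 1/count, and
    sparsely populated tail bins otherwise dominate the baseline/steepness
    trade-off.  The AUROC = 0.9 crossing, mapped back to the net-dG axis,
    is ``g09``; it is undefined when the fitted curve stays below 0.9 over
    the data range.
    """
    pts = [(r.net_dg, r.auroc_local) for r in records if r.auroc_local is not None]
    if not pts:
        raise ValueError("no records with a defined local AUROC")
    net = np.array([p[0] for p in pts])
    au = np.array([p[1] for p in pts])
    idx = np.floor(net / bin_width).astype(int)
    uniq = np.unique(idx)
    edges = uniq * bin_width
    means = np.array([au[idx == u].mean() for u in uniq])
    counts = np.array([(idx == u).sum() for u in uniq])
    if uniq.size < min_bins or (edges.max() - edges.min()) < min_span:
        raise ValueError(
            f"need >= {min_bins} bins spanning >= {min_span} kcal/mol, "
            f"have {uniq.size} over {edges.max() - edges.min():.1f}"
        )
    s = s_offset - (edges + bin_width / 2.0)
    if (s <= 0).any():
        keep = s > 0
        s, means, edges, counts = s[keep], means[keep], edges[keep], counts[keep]
    sigma = 1.0 / np.sqrt(counts) if weight_bins else None
    try:
        popt, _ = optimize.curve_fit(
            _hill, s, means,
            p0=[0.5, 4.0, min(10.0, s.max())],
            sigma=sigma,
            bounds=([0.3, 1e-6, 1e-6], [0.9, 20.0, 30.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Hill fit failed to converge: {exc}") from exc
    a0, h, s50 = (float(v) for v in popt)
    rss = float(((means - _hill(s, a0, h, s50)) ** 2).sum())
    s_max = float(s.max())
    if _hill(s_max, a0, h, s50) < 0.9:
        g09 = None
    else:
        q = (0.9 - a0) / (1.0 - a0)
        s_star = s50 * (q / (1 - q)) ** (1.0 / h)
        g09 = float(s_offset - s_star)
    return HillFit(
        a0=a0, hill=h, s50=s50, s_offset=s_offset, g09=g09, rss=rss,
        n_bins=int(s.size), bin_left_edges=edges, bin_means=means,
    )


def regress_fidelity(
    records: Sequence[FidelityRecord],
    region: str = "local",
):
    """OLS of log mean stem reactivity against net dG, per construct.

    ``region`` selects the local (variable) or distal (control) stems.  The
    log uses the standard pseudocount.  Requires >= 10 usable records and a
    non-degenerate net-dG spread.
    """
    from .lsc_stats import RegressionResult

    attr = f"stem_reactivity_{region}"
    pts = [
        (r.net_dg, math.log(getattr(r, attr) + LOG_PSEUDOCOUNT))
        for r in records
        if getattr(r, attr) is not None
    ]
    if len(pts) < 10:
        raise ValueError(f"need >= 10 records with defined {attr}, have {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if x.var() == 0:
        raise ValueError("degenerate regression: net dG has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=x.size,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_reactivity_tsv(profiles: Sequence[ReactivityProfile], path) -> None:
    """Write the long-format reactivity table consumed by the pipeline."""
    rows = []
    for p in profiles:
        depth = p.depth if p.depth is not None else np.full(len(p.sequence), -1)
        for i, base in enumerate(p.sequence, start=1):
            rows.append(
                (p.construct_id, i, base, p.reactivity[i - 1], int(depth[i - 1]))
            )
    pd.DataFrame(
        rows, columns=["construct_id", "position", "base", "mutation_fraction", "depth"]
    ).to_csv(path, sep="\t", index=False)


def read_reactivity_tsv(
    path,
    structures: dict[str, str] | None = None,
    local_positions: dict[str, Sequence[int]] | None = None,
) -> list[ReactivityProfile]:
    """Read a reactivity TSV (construct_id, position, base, mutation_fraction,
    optional depth) into profiles.

    ``structures`` maps construct id -> designed dot-bracket; constructs
    without a structure are skipped with a log message.  ``local_positions``
    maps construct id -> 1-based randomized-region positions.
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"construct_id", "position", "base", "mutation_fraction"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    structures = structures or {}
    local_positions = local_positions or {}
    out = []
    for cid, grp in df.groupby("construct_id", sort=True):
        grp = grp.sort_values("position")
        seq = "".join(grp["base"].astype(str))
        if str(cid) not in structures:
            log.info("read_reactivity_tsv: no designed structure for %s; skipped", cid)
            continue
        struct = parse_dotbracket(str(cid), seq, structures[str(cid)])
        depth = (
            grp["depth"].to_numpy(dtype=float) if "depth" in grp.columns else None
        )
        out.append(
            ReactivityProfile(
                construct_id=str(cid),
                sequence=struct.sequence,
                pair_table=struct.pair_table,
                reactivity=grp["mutation_fraction"].to_numpy(dtype=float),
                depth=depth,
                local_positions=frozenset(local_positions.get(str(cid), ())),
            )
        )
    return out
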