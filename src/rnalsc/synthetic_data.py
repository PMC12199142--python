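"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators make every pipeline stage testable without external data:

* :func:`simulate_structure_records` emulates a substructure database in
  which adjacent stem dG is a noisy linear function of loop dG
  (``stem = alpha * loop + beta + family_offset + noise``) — the generative
  picture behind compensation trends, binned regressions, and the rotation
  control.

* :func:`simulate_dms` emulates DMS reactivity under a two-state local
  unfolding model: each construct's variable region folds with probability
  given by a Hill function of its net stability, local stem positions draw
  reactivity from a paired/unpaired mixture accordingly, while distal
  positions always follow their designed state (the locality assumption
  under test).  Read-depth noise is binomial, as in mutation-counting data.

The two-state mixture is a modeling choice: intermediate reactivities in
real data may reflect partial folding or conformational ensembles rather
than a binary switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .library_design import DesignedConstruct
from .lsc_stats import SubstructureRecord
from .reactivity import ReactivityProfile

__all__ = [
    "DbSimConfig",
    "DmsSimConfig",
    "simulate_structure_records",
    "simulate_dms",
    "expected_auroc_curve",
    "random_nested_structure",
    "random_single_branch_structure",
]

_CANONICAL_PAIRS = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")]


def random_nested_structure(rng, target_len: int = 60) -> tuple[str, str]:
    """Random pseudoknot-free structure (sequence, dot-bracket).

    Built by recursive composition so multiloops, external runs, and every
    two-way junction type occur; pairs are always canonical.
    """
    def region(budget: int) -> tuple[list[str], list[str]]:
        if budget < 3:
            return [rng.choice("ACGU") for _ in range(budget)], ["."] * budget
        seq: list[str] = []
        db: list[str] = []
        while budget > 0:
            r = rng.random()
            if r < 0.4 or budget < 7:
                run = rng.randint(1, min(4, budget))
                seq += [rng.choice("ACGU") for _ in range(run)]
                db += ["."] * run
                budget -= run
            else:
                inner = rng.randint(3, budget - 4)
                stem_len = rng.randint(1, min(4, (budget - inner) // 2))
                pairs = [rng.choice(_CANONICAL_PAIRS) for _ in range(stem_len)]
                s_in, d_in = region(inner)
                seq += [p[0] for p in pairs] + s_in + [p[1] for p in reversed(pairs)]
                db += ["("] * stem_len + d_in + [")"] * stem_len
                budget -= inner + 2 * stem_len
        return seq, db

    seq, db = region(target_len)
    return "".join(seq), "".join(db)


def random_single_branch_structure(
    rng, min_len: int = 20, max_len: int = 80, big_loops: bool = False
) -> tuple[str, str]:
    """Random single-branch structure (one helix path, no multiloop).

    Grown inside out from a hairpin loop by stacking pairs and inserting
    bulges/internal loops; with ``big_loops``, occasional loops larger than
    the tabulated size-30 limit exercise the length extrapolation.
    """
    seq = [rng.choice("ACGU") for _ in range(rng.randint(3, 8))]
    db = ["."] * len(seq)
    target = rng.randint(min_len, max_len)
    while len(seq) < target:
        r = rng.random()
        b5, b3 = rng.choice(_CANONICAL_PAIRS)
        if r < 0.55:  # stack a pair
            seq = [b5] + seq + [b3]
            db = ["("] + db + [")"]
        elif r < 0.78:  # bulge on one side, then close
            size = rng.randint(1, 6) if not (big_loops and rng.random() < 0.1) else rng.randint(31, 45)
            run = [rng.choice("ACGU") for _ in range(size)]
            if rng.random() < 0.5:
                seq = [b5] + run + seq + [b3]
                db = ["("] + ["."] * size + db + [")"]
            else:
                seq = [b5] + seq + run + [b3]
                db = ["("] + db + ["."] * size + [")"]
        else:  # internal loop, then close
            s1, s2 = rng.randint(1, 5), rng.randint(1, 5)
            if big_loops and rng.random() < 0.05:
                s1 = rng.randint(28, 40)
            l5 = [rng.choice("ACGU") for _ in range(s1)]
            l3 = [rng.choice("ACGU") for _ in range(s2)]
            seq = [b5] + l5 + seq + l3 + [b3]
            db = ["("] + ["."] * s1 + db + ["."] * s2 + [")"]
    for _ in range(rng.randint(0, 4)):  # unpaired external tail
        seq.append(rng.choice("ACGU"))
        db.append(".")
    return "".join(seq), "".join(db)


@dataclass
class DbSimConfig:
    """Generative settings for a synthetic substructure database."""

    n_records: int = 2000
    loop_types: tuple[str, ...] = ("hairpin",)
    #: compensation slope and intercept: stem = alpha * loop + beta + eps
    alpha: float = -0.8
    beta: float = -2.0
    sigma: float = 1.0  # noise SD, kcal/mol
    #: loop dG sampled from an exponential truncated to this range, kcal/mol
    loop_dg_range: tuple[float, float] = (0.5, 12.0)
    loop_dg_scale: float = 3.0
    loops_per_structure: int = 5  # > 3 keeps structures rotation-eligible
    family_offsets: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.loops_per_structure < 1:
            raise ValueError("loops_per_structure must be >= 1")


def _truncated_exponential(
    rng: np.random.Generator, n: int, lo: float, hi: float, scale: float
) -> np.ndarray:
    # inverse-CDF sampling of Exp(scale) conditioned on [lo, hi]
    u = rng.random(n)
    a = 1.0 - math.exp(-(lo) / scale)
    b = 1.0 - math.exp(-(hi) / scale)
    return -scale * np.log(1.0 - (a + u * (b - a)))


def simulate_structure_records(config: DbSimConfig) -> list[SubstructureRecord]:
    """Generate substructure records under the linear compensation model.

    Records are grouped into synthetic structures of
    ``loops_per_structure`` loops each (per loop type), with disjoint stem
    labels within a structure, so rotation-control eligibility and
    adjacency checks behave as on real decompositions.  Hairpins carry one
    stem energy; bulges and internal loops two (each drawn independently
    around the same linear mean).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.loop_dg_range
    families = sorted(config.family_offsets) or [""]
    records: list[SubstructureRecord] = []
    prefix = {"hairpin": "H", "bulge": "B", "internal": "I"}
    for loop_type in config.loop_types:
        n_structures = math.ceil(config.n_records / config.loops_per_structure)
        made = 0
        for s_idx in range(n_structures):
            family = families[s_idx % len(families)]
            offset = config.family_offsets.get(family, 0.0)
            k = min(config.loops_per_structure, config.n_records - made)
            loop_dgs = _truncated_exponential(rng, k, lo, hi, config.loop_dg_scale)
            for i in range(k):
                loop_dg = float(loop_dgs[i])
                mean_stem = config.alpha * loop_dg + config.beta + offset
                if loop_type == "hairpin":
                    stem_dgs = (float(mean_stem + rng.normal(0, config.sigma)),)
                    stem_labels = (f"S{i + 1}",)
                else:
                    stem_dgs = (
                        float(mean_stem + rng.normal(0, config.sigma)),
                        float(mean_stem + rng.normal(0, config.sigma)),
                    )
                    stem_labels = (f"S{2 * i + 1}", f"S{2 * i + 2}")
                records.append(
                    SubstructureRecord(
                        structure_id=f"sim_{loop_type}_{s_idx:05d}",
                        loop_label=f"{prefix[loop_type]}{i + 1}",
                        loop_type=loop_type,
                        loop_dg=loop_dg,
                        stem_dgs=stem_dgs,
                        stem_labels=stem_labels,
                        family=family,
                    )
                )
            made += k
    return records


@dataclass
class DmsSimConfig:
    """Two-state local-unfolding model for simulated DMS reactivity.

    The variable region of a construct folds with probability
    f(s) = s^h / (s50^h + s^h), s = s_offset - net dG; the unfolded
    fraction is 1 - f(s).  Paired and unpaired nucleotides draw true
    mutation rates from log-normal distributions with the configured means
    (typical DMS mutation-fraction scales); observed reactivity adds
    binomial counting noise at Poisson-distributed read depth.
    """

    constructs: Sequence[DesignedConstruct] = ()
    h_true: float = 4.0
    s50_true: float = 14.0
    s_offset: float = 10.0
    paired_mean: float = 0.01
    paired_log_sd: float = 0.5
    unpaired_mean: float = 0.10
    unpaired_log_sd: float = 0.5
    #: multiplicative depression of loop reactivity in the folded state
    loop_folded_factor: float = 0.8
    read_depth: float = 5000.0
    seed: int = 0

    def __post_init__(self):
        if self.unpaired_mean <= self.paired_mean:
            raise ValueError("unpaired mean reactivity must exceed paired mean")
        if self.read_depth < 1:
            raise ValueError("read depth must be >= 1")

    @property
    def g09_true(self) -> float | None:
        """Net dG at which expected folded fraction-driven AUROC crosses 0.9,
        under the ideal baseline AUROC(unfolded) = 0.5 and plateau 1.0."""
        q = (0.9 - 0.5) / (1.0 - 0.5)
        s_star = self.s50_true * (q / (1 - q)) ** (1.0 / self.h_true)
        return self.s_offset - s_star

    def unfolded_fraction(self, net_dg: float) -> float:
        s = self.s_offset - net_dg
        if s <= 0:
            return 1.0
        return 1.0 - s**self.h_true / (self.s50_true**self.h_true + s**self.h_true)


def _lognormal_mu(mean: float, log_sd: float) -> float:
    return math.log(mean) - log_sd**2 / 2.0


def simulate_dms(config: DmsSimConfig) -> list[ReactivityProfile]:
    """Simulate one reactivity profile per designed construct.

    Local stem positions draw their true rate from the paired distribution
    with probability f(s) (folded) and from the unpaired distribution
    otherwise; local loop positions draw from the unpaired distribution,
    depressed by ``loop_folded_factor`` when folded; distal positions draw
    from their designed state's distribution regardless of the local state.
    """
    rng = np.random.default_rng(config.seed)
    mu_p = _lognormal_mu(config.paired_mean, config.paired_log_sd)
    mu_u = _lognormal_mu(config.unpaired_mean, config.unpaired_log_sd)
    profiles = []
    for c in config.constructs:
        struct = c.structure()
        n = struct.length
        p_unfold = config.unfolded_fraction(c.net_dg)
        local = np.zeros(n, dtype=bool)
        for p in c.local_positions:
            local[p - 1] = True
        paired = np.array([struct.pair_table[i] != 0 for i in range(1, n + 1)])
        unfolded = rng.random(n) < p_unfold  # per-position state draw
        draw_p = np.exp(rng.normal(mu_p, config.paired_log_sd, n))
        draw_u = np.exp(rng.normal(mu_u, config.unpaired_log_sd, n))
        rate = np.where(paired, draw_p, draw_u)
        # local stems: mixture between paired and unpaired rates
        sel = local & paired & unfolded
        rate[sel] = draw_u[sel]
        # local loops: slightly depressed when folded
        sel = local & ~paired & ~unfolded
        rate[sel] = draw_u[sel] * config.loop_folded_factor
        rate = np.clip(rate, 0.0, 1.0)
        depth = np.maximum(rng.poisson(config.read_depth, n), 1)
        observed = rng.binomial(depth, rate) / depth
        profiles.append(
            ReactivityProfile(
                construct_id=c.id,
                sequence=struct.sequence,
                pair_table=struct.pair_table,
                reactivity=observed,
                depth=depth.astype(float),
                local_positions=frozenset(c.local_positions),
            )
        )
    return profiles


def expected_auroc_curve(
    config: DmsSimConfig,
    net_dg_grid: Sequence[float],
    n_draws: int = 100_000,
    n_negatives_ratio: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Monte-Carlo expectation of the local AUROC on a net-dG grid.

    At each grid point, positives (local loop nucleotides) and negatives
    (local stem nucleotides) are drawn from the generative model including
    depth noise, and the rank-based AUROC of the large samples approximates
    the expected value.  Used as an oracle for recovery tests.
    """
    from .reactivity import _rank_auroc

    rng = np.random.default_rng(config.seed if seed is None else seed)
    mu_p = _lognormal_mu(config.paired_mean, config.paired_log_sd)
    mu_u = _lognormal_mu(config.unpaired_mean, config.unpaired_log_sd)
    n_neg = int(n_draws * n_negatives_ratio)
    out = []
    for net in net_dg_grid:
        p_unfold = config.unfolded_fraction(float(net))
        unfolded_neg = rng.random(n_neg) < p_unfold
        neg_rate = np.where(
            unfolded_neg,
            np.exp(rng.normal(mu_u, config.unpaired_log_sd, n_neg)),
            np.exp(rng.normal(mu_p, config.paired_log_sd, n_neg)),
        )
        folded_pos = rng.random(n_draws) >= p_unfold
        pos_rate = np.exp(rng.normal(mu_u, config.unpaired_log_sd, n_draws))
        pos_rate[folded_pos] *= config.loop_folded_factor
        depth_n = np.maximum(rng.poisson(config.read_depth, n_neg), 1)
        depth_p = np.maximum(rng.poisson(config.read_depth, n_draws), 1)
        neg = rng.binomial(depth_n, np.clip(neg_rate, 0, 1)) / depth_n
        pos = rng.binomial(depth_p, np.clip(pos_rate, 0, 1)) / depth_p
        out.append(_rank_auroc(pos, neg))
    return np.array(out)
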