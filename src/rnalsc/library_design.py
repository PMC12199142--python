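"""Randomized RNA construct libraries on a triply-bulged hairpin template.

Each construct is a single-branch hairpin with four stems (S1 outermost to
S4 closing the apical loop) separated by three single-stranded slots, plus
unpaired 5'/3' flanks.  One slot is the *variable region* whose loop and
flanking stem(s) are randomized to span a wide range of net dG:

* hairpin library: the apical hairpin loop + S4 vary;
* bulge library: the middle bulge (slot 2) + S2 and S3 vary;
* internal-loop library: slot 2 becomes an internal loop + S2 and S3 vary.

All other slots use constant-energy stems (fixed GC fraction, G:C/C:G
closing pairs, no G:U) and fixed loops, so that only the variable region's
stability varies between members.  Loops use the {A, C} alphabet so every
loop position is informative under DMS probing.

Library-level constraints: pairwise sequence distance of at least 20
(positional mismatches over the shorter length plus the length difference),
and sequence lengths within +/-20% of the realized mean.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energies import TurnerParameters, annotate_structure_energies
from .structures import RnaStructure, decompose, parse_dotbracket

__all__ = [
    "TemplateSpec",
    "DesignConstraints",
    "DesignedConstruct",
    "DesignError",
    "make_constant_stem",
    "sample_variable_region",
    "generate_library",
    "sequence_distance",
    "library_to_files",
]

log = logging.getLogger(__name__)


class DesignError(ValueError):
    pass


@dataclass
class DesignConstraints:
    """Composition, length, and distance constraints for library members."""

    stem_len: tuple[int, int] = (4, 12)
    hairpin_len: tuple[int, int] = (3, 11)
    bulge_len: tuple[int, int] = (1, 9)
    internal_len: tuple[int, int] = (1, 9)  # total across both sides, each >= 1
    loop_alphabet: str = "AC"
    min_hamming: int = 20
    length_window: float = 0.2
    constant_gc_fraction: float = 0.6
    #: GC-fraction grid for variable stems; includes 0 so very weak stems
    #: (and hence positive net dG) are represented
    variable_gc_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    #: G:U pair count grid for variable stems
    variable_gu_grid: tuple[int, ...] = (0, 1, 2, 3)
    max_attempts_per_construct: int = 200


@dataclass
class TemplateSpec:
    """Triply-bulged hairpin layout with one variable slot.

    ``variable_slot`` is ``"hairpin"``, ``"bulge"``, or ``"internal"``.  The
    flank sequences and constant-slot geometries are package defaults; real
    experiments substitute their own leader/primer sites.
    """

    variable_slot: str = "hairpin"
    flank5: str = "GGAACAACAA"
    flank3: str = "AAAGAAACAACAACAAC"
    constant_stem_lengths: tuple[int, int, int, int] = (10, 5, 5, 5)
    constant_bulge: str = "A"
    constant_hairpin: str = "AACAA"

    def __post_init__(self):
        if self.variable_slot not in ("hairpin", "bulge", "internal"):
            raise DesignError(f"unknown variable_slot '{self.variable_slot}'")


@dataclass
class DesignedConstruct:
    """One library member: sequence, designed structure, and energies."""

    id: str
    sequence: str
    dotbracket: str
    loop_type: str
    local_positions: tuple[int, ...]  # 1-based, variable loop + flanking stems
    loop_label: str
    loop_dg: float
    stem_dgs: tuple[float, ...]
    stem_labels: tuple[str, ...] = ()

    @property
    def net_dg(self) -> float:
        return self.loop_dg + float(np.mean(self.stem_dgs))

    def structure(self) -> RnaStructure:
        return parse_dotbracket(self.id, self.sequence, self.dotbracket)


_PAIRS_GC = [("G", "C"), ("C", "G")]
_PAIRS_AU = [("A", "U"), ("U", "A")]
_PAIRS_GU = [("G", "U"), ("U", "G")]


def make_constant_stem(
    length: int, rng: random.Random, gc_fraction: float = 0.6
) -> list[tuple[str, str]]:
    """Sample a constant-energy stem as an outer->inner base-pair list.

    Both closing pairs are G:C or C:G, the GC fraction is exactly
    ``gc_fraction`` (an error if not an integer pair count), and no G:U
    pairs are used; the remaining pairs are A:U/U:A in random positions and
    orientations.
    """
    n_gc = gc_fraction * length
    if abs(n_gc - round(n_gc)) > 1e-9:
        raise DesignError(
            f"GC fraction {gc_fraction} infeasible at stem length {length}: "
            f"non-integer pair count"
        )
    n_gc = round(n_gc)
    if n_gc < 2 and length >= 2:
        raise DesignError(
            f"GC fraction {gc_fraction} at length {length} leaves no G:C closing pairs"
        )
    interior = [rng.choice(_PAIRS_GC) for _ in range(n_gc - 2)]
    interior += [rng.choice(_PAIRS_AU) for _ in range(length - n_gc)]
    rng.shuffle(interior)
    return [rng.choice(_PAIRS_GC), *interior, rng.choice(_PAIRS_GC)]


def _variable_stem(length: int, gc_fraction: float, n_gu: int, rng: random.Random):
    n_gc = round(gc_fraction * length)
    n_gu = min(n_gu, length - n_gc)
    pairs = [rng.choice(_PAIRS_GC) for _ in range(n_gc)]
    pairs += [rng.choice(_PAIRS_GU) for _ in range(n_gu)]
    pairs += [rng.choice(_PAIRS_AU) for _ in range(length - n_gc - n_gu)]
    rng.shuffle(pairs)
    return pairs


def sample_variable_region(
    loop_type: str, rng: random.Random, constraints: DesignConstraints
) -> tuple[list[str], list[list[tuple[str, str]]]]:
    """Draw a random variable loop plus its flanking stem(s).

    Returns ``(loop_strands, stems)``: one loop strand and one stem for
    hairpins; one strand and two stems for bulges; two strands and two stems
    for internal loops.  Loop sequences use the constrained {A, C} alphabet;
    stems vary in length, GC fraction, and G:U pair count over the
    configured grids.
    """
    def draw_loop(size: int) -> str:
        return "".join(rng.choice(constraints.loop_alphabet) for _ in range(size))

    def draw_stem():
        length = rng.randint(*constraints.stem_len)
        gc = rng.choice(constraints.variable_gc_grid)
        gu = rng.choice(constraints.variable_gu_grid)
        return _variable_stem(length, gc, gu, rng)

    if loop_type == "hairpin":
        size = rng.randint(*constraints.hairpin_len)
        return [draw_loop(size)], [draw_stem()]
    if loop_type == "bulge":
        size = rng.randint(*constraints.bulge_len)
        return [draw_loop(size)], [draw_stem(), draw_stem()]
    if loop_type == "internal":
        # the size range counts total unpaired nucleotides, split across the
        # two sides with at least one on each
        lo, hi = constraints.internal_len
        total = rng.randint(max(2, lo), hi)
        n5 = rng.randint(1, total - 1)
        return [draw_loop(n5), draw_loop(total - n5)], [draw_stem(), draw_stem()]
    raise DesignError(f"unknown loop type '{loop_type}'")


def sequence_distance(a: str, b: str) -> int:
    """Distance between possibly unequal-length sequences.

    Positional mismatches over the shorter length, plus the length
    difference (each overhanging position counts as one mismatch).
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    return sum(x != y for x, y in zip(short, long_)) + (len(long_) - len(short))


def _assemble(template: TemplateSpec, stems, slots, hairpin: str):
    """Build (sequence, dotbracket, variable_marker_pos) from parts.

    ``stems`` is the outer->inner list of 4 base-pair lists; ``slots`` the 3
    single-stranded slot contents as (strand5, strand3) tuples.
    """
    left, right, db_left, db_right = [], [], [], []
    left.append(template.flank5)
    db_left.append("." * len(template.flank5))
    for k in range(4):
        s5 = "".join(p[0] for p in stems[k])
        s3 = "".join(p[1] for p in reversed(stems[k]))
        left.append(s5)
        db_left.append("(" * len(s5))
        right.insert(0, s3)
        db_right.insert(0, ")" * len(s3))
        if k < 3:
            slot5, slot3 = slots[k]
            left.append(slot5)
            db_left.append("." * len(slot5))
            right.insert(0, slot3)
            db_right.insert(0, "." * len(slot3))
    seq = "".join(left) + hairpin + "".join(right) + template.flank3
    db = "".join(db_left) + "." * len(hairpin) + "".join(db_right) + "." * len(template.flank3)
    return seq, db


def _sample_construct(
    template: TemplateSpec,
    constraints: DesignConstraints,
    rng: random.Random,
    cid: str,
    params: TurnerParameters,
) -> DesignedConstruct:
    slot = template.variable_slot
    lens = template.constant_stem_lengths
    gc = constraints.constant_gc_fraction
    if slot == "hairpin":
        (loop,), (var_stem,) = sample_variable_region("hairpin", rng, constraints)
        stems = [make_constant_stem(lens[k], rng, gc) for k in range(3)] + [var_stem]
        slots = [(template.constant_bulge, ""), (template.constant_bulge, ""),
                 (template.constant_bulge, "")]
        hairpin = loop
    else:
        loops, (stem_a, stem_b) = sample_variable_region(slot, rng, constraints)
        stems = [
            make_constant_stem(lens[0], rng, gc),
            stem_a,
            stem_b,
            make_constant_stem(lens[3], rng, gc),
        ]
        var_slot_content = (loops[0], "") if slot == "bulge" else (loops[0], loops[1])
        slots = [(template.constant_bulge, ""), var_slot_content,
                 (template.constant_bulge, "")]
        hairpin = template.constant_hairpin
    seq, db = _assemble(template, stems, slots, hairpin)
    struct = parse_dotbracket(cid, seq, db)
    sset = decompose(struct)
    energies = {e.label: e for e in annotate_structure_energies(struct, params, sset)}
    # locate the variable loop in the decomposition
    if slot == "hairpin":
        loop_obj = sset.hairpins[0]
    else:
        # slot 2 loop: the one whose outer pair belongs to stem S2 (variable)
        var_outer = sset.stems[1].pairs[-1]
        candidates = [
            l for l in (*sset.bulges, *sset.internal_loops)
            if l.outer_pair == var_outer
        ]
        loop_obj = candidates[0]
    stem_labels = tuple(sset.adjacency[loop_obj.label])
    loop_e = energies[loop_obj.label]
    stem_es = [energies[lbl] for lbl in stem_labels]
    if not loop_e.scorable or any(not e.scorable for e in stem_es):
        raise DesignError(f"{cid}: unscorable variable region")
    local = set(loop_obj.loop_positions)
    for lbl in stem_labels:
        local.update(sset.by_label(lbl).positions)
    return DesignedConstruct(
        id=cid,
        sequence=seq,
        dotbracket=db,
        loop_type=slot,
        local_positions=tuple(sorted(local)),
        loop_label=loop_obj.label,
        loop_dg=loop_e.dg,
        stem_dgs=tuple(e.dg for e in stem_es),
        stem_labels=stem_labels,
    )


def generate_library(
    template: TemplateSpec,
    n: int,
    seed: int,
    constraints: DesignConstraints | None = None,
    params: TurnerParameters | None = None,
    enforce_distance: bool = True,
) -> list[DesignedConstruct]:
    """Generate ``n`` constraint-satisfying constructs, deterministically.

    Rejection sampling enforces the pairwise distance floor; after
    generation, constructs outside the +/-20% window around the realized
    mean length are filtered out (so the returned library may be slightly
    smaller than ``n``).  Identical seed and configuration reproduce the
    library exactly.
    """
    from .energies import load_turner_params

    if n < 1:
        raise DesignError("n must be >= 1")
    constraints = constraints or DesignConstraints()
    params = params or load_turner_params()
    rng = random.Random(seed)
    accepted: list[DesignedConstruct] = []
    enc: list[np.ndarray] = []  # uint8-encoded, zero-padded sequences
    max_len = 0
    budget = constraints.max_attempts_per_construct * n
    attempts = 0
    while len(accepted) < n:
        if attempts >= budget:
            raise DesignError(
                f"exhausted {budget} attempts; achieved {len(accepted)}/{n} constructs"
            )
        attempts += 1
        cand = _sample_construct(
            template, constraints, rng, f"{template.variable_slot}_{len(accepted):05d}", params
        )
        if enforce_distance and accepted:
            a = np.frombuffer(cand.sequence.encode(), dtype=np.uint8)
            width = max(max_len, a.size)
            mat = np.zeros((len(enc), width), dtype=np.uint8)
            for i, e in enumerate(enc):
                mat[i, : e.size] = e
            row = np.zeros(width, dtype=np.uint8)
            row[: a.size] = a
            dists = (mat != row).sum(axis=1)
            if dists.min() < constraints.min_hamming:
                continue
        accepted.append(cand)
        e = np.frombuffer(cand.sequence.encode(), dtype=np.uint8)
        enc.append(e)
        max_len = max(max_len, e.size)
    lengths = np.array([len(c.sequence) for c in accepted], dtype=float)
    mean_len = lengths.mean()
    window = constraints.length_window
    keep = np.abs(lengths - mean_len) <= window * mean_len
    dropped = int((~keep).sum())
    if dropped:
        log.info(
            "generate_library: filtered %d construct(s) outside +/-%d%% of mean length %.1f",
            dropped, round(window * 100), mean_len,
        )
    return [c for c, k in zip(accepted, keep) if k]


def library_to_files(library, fasta_path, dotbracket_path, manifest_path, seed=None) -> None:
    """Write FASTA, a dot-bracket table, and the TSV manifest for a library."""
    with open(fasta_path, "w") as fa:
        for c in library:
            fa.write(f">{c.id}\n{c.sequence}\n")
    with open(dotbracket_path, "w") as dbf:
        for c in library:
            dbf.write(f"{c.id}\t{c.sequence}\t{c.dotbracket}\n")
    rows = [
        {
            "construct_id": c.id,
            "loop_type": c.loop_type,
            "loop_label": c.loop_label,
            "loop_dg": c.loop_dg,
            "stem_dgs": ",".join(f"{v:.2f}" for v in c.stem_dgs),
            "net_dg": c.net_dg,
            "local_positions": ",".join(str(p) for p in c.local_positions),
            "length": len(c.sequence),
        }
        for c in library
    ]
    df = pd.DataFrame(rows)
    if seed is not None:
        df.attrs["seed"] = seed
    header = f"# rng_seed={seed}\n" if seed is not None else ""
    with open(manifest_path, "w") as mf:
        mf.write(header)
        df.to_csv(mf, sep="\t", index=False)
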