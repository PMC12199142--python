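"""RNA secondary-structure containers, dot-bracket parsing, and substructure
decomposition.

The decomposition splits a nested (pseudoknot-free) secondary structure into
stems (maximal stacked helices), hairpin loops, bulges, internal loops, and
unscored multiloop/external regions.  All coordinates are 1-based and ranges
are inclusive, matching the structure-type (.st) file convention.

Per-position structure codes:

======  =====================================================
code    meaning
======  =====================================================
S       paired (part of a stem)
H       hairpin loop
B       bulge (one-sided two-way junction)
I       internal loop (two-sided two-way junction)
M       multiloop (junction with >= 3 emanating helices)
X       external unpaired run between top-level helices
E       unpaired 5'/3' end
======  =====================================================
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RnaStructure",
    "Stem",
    "HairpinLoop",
    "Bulge",
    "InternalLoop",
    "SubstructureSet",
    "StructureError",
    "parse_dotbracket",
    "decompose",
    "read_st",
    "write_ste",
    "export_hard_constraints",
]

#: bracket alphabets; the primary page is scored, the rest flag pseudoknots
_OPEN = "([{<ABCDEFG"
_CLOSE = ")]}>abcdefg"


class StructureError(ValueError):
    """Raised for malformed structures or structure files."""


@dataclass
class RnaStructure:
    """A secondary structure: sequence, pairing, and per-position codes.

    ``pair_table`` is 1-based: ``pair_table[i]`` is the partner of position
    ``i`` (0 when unpaired); index 0 is a placeholder.  ``position_codes`` is
    a string of per-position substructure codes (see module docstring).
    """

    id: str
    sequence: str
    pair_table: list[int]
    position_codes: str = ""
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    pseudoknot_positions: frozenset[int] = frozenset()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def dotbracket(self) -> str:
        out = []
        for i in range(1, self.length + 1):
            j = self.pair_table[i]
            out.append("." if j == 0 else ("(" if j > i else ")"))
        return "".join(out)

    def validate(self) -> None:
        n = self.length
        if len(self.pair_table) != n + 1:
            raise StructureError(f"{self.id}: pair_table length != sequence length + 1")
        for i in range(1, n + 1):
            j = self.pair_table[i]
            if j == i:
                raise StructureError(f"{self.id}: position {i} pairs with itself")
            if j and self.pair_table[j] != i:
                raise StructureError(f"{self.id}: pair table is not an involution at {i}")
        # non-crossing check via a stack
        stack: list[int] = []
        for i in range(1, n + 1):
            j = self.pair_table[i]
            if j > i:
                stack.append(j)
            elif 0 < j < i:
                if not stack or stack[-1] != i:
                    raise StructureError(f"{self.id}: crossing base pairs at {i}")
                stack.pop()
        if self.position_codes and len(self.position_codes) != n:
            raise StructureError(f"{self.id}: position_codes length mismatch")


@dataclass
class Stem:
    """A maximal run of consecutively stacked base pairs (length >= 1)."""

    label: str
    strand5: tuple[int, int]  # inclusive 1-based range on the 5' strand
    strand3: tuple[int, int]
    pairs: list[tuple[int, int]]  # ordered outermost -> innermost

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def positions(self) -> list[int]:
        return list(range(self.strand5[0], self.strand5[1] + 1)) + list(
            range(self.strand3[0], self.strand3[1] + 1)
        )


@dataclass
class HairpinLoop:
    label: str
    closing_pair: tuple[int, int]
    loop_positions: list[int]

    @property
    def size(self) -> int:
        return len(self.loop_positions)


@dataclass
class Bulge:
    label: str
    outer_pair: tuple[int, int]
    inner_pair: tuple[int, int]
    bulged_side: str  # "5p" or "3p"
    bulge_positions: list[int]

    @property
    def size(self) -> int:
        return len(self.bulge_positions)

    @property
    def loop_positions(self) -> list[int]:
        return self.bulge_positions


@dataclass
class InternalLoop:
    label: str
    outer_pair: tuple[int, int]
    inner_pair: tuple[int, int]
    side5_positions: list[int]
    side3_positions: list[int]

    @property
    def sizes(self) -> tuple[int, int]:
        return (len(self.side5_positions), len(self.side3_positions))

    @property
    def loop_positions(self) -> list[int]:
        return self.side5_positions + self.side3_positions


@dataclass
class SubstructureSet:
    """Typed decomposition of a structure plus loop->stem adjacency.

    ``adjacency`` maps a loop label to the labels of its flanking stems:
    exactly one stem for hairpins, exactly two (outer, inner) for bulges and
    internal loops.  ``other_regions`` holds unscored multiloop/external runs
    as ``(label, positions)`` tuples.
    """

    stems: list[Stem] = field(default_factory=list)
    hairpins: list[HairpinLoop] = field(default_factory=list)
    bulges: list[Bulge] = field(default_factory=list)
    internal_loops: list[InternalLoop] = field(default_factory=list)
    other_regions: list[tuple[str, list[int]]] = field(default_factory=list)
    adjacency: dict[str, list[str]] = field(default_factory=dict)

    def loops(self) -> list[HairpinLoop | Bulge | InternalLoop]:
        return [*self.hairpins, *self.bulges, *self.internal_loops]

    def by_label(self, label: str):
        for group in (self.stems, self.hairpins, self.bulges, self.internal_loops):
            for item in group:
                if item.label == label:
                    return item
        raise KeyError(label)


def parse_dotbracket(id: str, sequence: str, db: str) -> RnaStructure:
    """Parse a dot-bracket string into an :class:`RnaStructure`.

    Primary-page brackets ``()`` define the nested pairing.  Extended
    brackets (``[]{}<>``, ``Aa``...) denote pseudoknot pairs; these are
    recorded as unpaired with a warning, and the analysis proceeds on the
    nested skeleton.
    """
    if len(sequence) != len(db):
        raise StructureError(
            f"{id}: sequence length {len(sequence)} != structure length {len(db)}"
        )
    n = len(db)
    pair_table = [0] * (n + 1)
    stacks: dict[int, list[int]] = {}
    pk_positions: set[int] = set()
    for pos, ch in enumerate(db, start=1):
        if ch == ".":
            continue
        page_open = _OPEN.find(ch)
        page_close = _CLOSE.find(ch)
        if page_open >= 0:
            stacks.setdefault(page_open, []).append(pos)
        elif page_close >= 0:
            stack = stacks.get(page_close, [])
            if not stack:
                raise StructureError(f"{id}: unmatched '{ch}' at position {pos}")
            i = stack.pop()
            if page_close == 0:
                pair_table[i] = pos
                pair_table[pos] = i
            else:
                pk_positions.update((i, pos))
        else:
            raise StructureError(f"{id}: invalid structure character '{ch}' at position {pos}")
    for page, stack in stacks.items():
        if stack:
            raise StructureError(
                f"{id}: unclosed '{_OPEN[page]}' at position {stack[-1]}"
            )
    struct = RnaStructure(
        id=id,
        sequence=sequence.upper().replace("T", "U"),
        pair_table=pair_table,
        pseudoknot_positions=frozenset(pk_positions),
    )
    if pk_positions:
        struct.warnings.append(
            f"{len(pk_positions) // 2} pseudoknot pair(s) dropped to unpaired"
        )
    struct.validate()
    struct.position_codes = _codes_from_decomposition(struct, decompose(struct))
    return struct


def decompose(structure: RnaStructure) -> SubstructureSet:
    """Decompose a nested structure into typed substructures with adjacency."""
    pt = structure.pair_table
    n = structure.length
    sset = SubstructureSet()

    # --- stems: maximal stacked runs -------------------------------------
    stem_of_pair: dict[tuple[int, int], Stem] = {}
    seen: set[int] = set()
    for i in range(1, n + 1):
        j = pt[i]
        if j <= i or i in seen:
            continue
        pairs = [(i, j)]
        while True:
            k, l = pairs[-1]
            if k + 1 <= n and pt[k + 1] == l - 1 and l - 1 > k + 1:
                pairs.append((k + 1, l - 1))
            else:
                break
        seen.update(p for p, _ in pairs)
        stem = Stem(
            label=f"S{len(sset.stems) + 1}",
            strand5=(pairs[0][0], pairs[-1][0]),
            strand3=(pairs[-1][1], pairs[0][1]),
            pairs=pairs,
        )
        sset.stems.append(stem)
        for p in pairs:
            stem_of_pair[p] = stem

    # --- loops: classify the region enclosed by each innermost pair -------
    def children_of(lo: int, hi: int) -> list[tuple[int, int]]:
        kids = []
        k = lo
        while k <= hi:
            if pt[k] > k:
                kids.append((k, pt[k]))
                k = pt[k] + 1
            else:
                k += 1
        return kids

    for stem in sset.stems:
        p, q = stem.pairs[-1]  # innermost pair
        kids = children_of(p + 1, q - 1)
        if not kids:
            hp = HairpinLoop(
                label=f"H{len(sset.hairpins) + 1}",
                closing_pair=(p, q),
                loop_positions=list(range(p + 1, q - 1 + 1)),
            )
            sset.hairpins.append(hp)
            sset.adjacency[hp.label] = [stem.label]
        elif len(kids) == 1:
            (k, l) = kids[0]
            side5 = list(range(p + 1, k - 1 + 1))
            side3 = list(range(l + 1, q - 1 + 1))
            inner_stem = stem_of_pair[(k, l)]
            if side5 and side3:
                il = InternalLoop(
                    label=f"I{len(sset.internal_loops) + 1}",
                    outer_pair=(p, q),
                    inner_pair=(k, l),
                    side5_positions=side5,
                    side3_positions=side3,
                )
                sset.internal_loops.append(il)
                sset.adjacency[il.label] = [stem.label, inner_stem.label]
            else:
                bl = Bulge(
                    label=f"B{len(sset.bulges) + 1}",
                    outer_pair=(p, q),
                    inner_pair=(k, l),
                    bulged_side="5p" if side5 else "3p",
                    bulge_positions=side5 or side3,
                )
                sset.bulges.append(bl)
                sset.adjacency[bl.label] = [stem.label, inner_stem.label]
        else:  # multiloop: record unpaired runs, never scored
            positions = [
                x for x in range(p + 1, q) if pt[x] == 0 and _enclosing_pair(pt, x) == (p, q)
            ]
            if positions:
                sset.other_regions.append((f"M{_count(sset, 'M') + 1}", positions))

    # --- external runs -----------------------------------------------------
    top_unpaired = [
        x for x in range(1, n + 1) if pt[x] == 0 and _enclosing_pair(pt, x) is None
    ]
    for run in _runs(top_unpaired):
        is_end = run[0] == 1 or run[-1] == n
        label = ("E" if is_end else "X") + str(_count(sset, "E" if is_end else "X") + 1)
        sset.other_regions.append((label, run))
    return sset


def _enclosing_pair(pt: Sequence[int], x: int) -> tuple[int, int] | None:
    """Closest base pair (i, j) with i < x < j, or None at top level."""
    best = None
    for i in range(1, x):
        if x < pt[i] and (best is None or i > best[0]):
            best = (i, pt[i])
    return best


def _runs(positions: Iterable[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for p in positions:
        if runs and p == runs[-1][-1] + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    return runs


def _count(sset: SubstructureSet, prefix: str) -> int:
    return sum(1 for lbl, _ in sset.other_regions if lbl.startswith(prefix))


def _codes_from_decomposition(structure: RnaStructure, sset: SubstructureSet) -> str:
    codes = ["E"] * structure.length

    def put(positions: Iterable[int], code: str) -> None:
        for p in positions:
            codes[p - 1] = code

    for stem in sset.stems:
        put(stem.positions, "S")
    for hp in sset.hairpins:
        put(hp.loop_positions, "H")
    for bl in sset.bulges:
        put(bl.bulge_positions, "B")
    for il in sset.internal_loops:
        put(il.loop_positions, "I")
    for label, positions in sset.other_regions:
        put(positions, label[0])
    return "".join(codes)


def compute_codes(structure: RnaStructure) -> str:
    """Recompute per-position codes from the pair table."""
    return _codes_from_decomposition(structure, decompose(structure))


# ---------------------------------------------------------------------------
# structure-type (.st / .ste) files
# ---------------------------------------------------------------------------

_SEGMENT_RE = re.compile(r"^[SHBIMXE]\d+\s")


def read_st(path: str | Path) -> RnaStructure:
    """Read a bpRNA-style structure-type (.st) or energy-annotated (.ste) file.

    Mandatory content: optional ``#`` header lines, then the sequence line,
    the dot-bracket line, and the per-position structure-code line.  Any
    following segment/annotation lines are preserved in ``metadata``.  The
    file's code line is cross-checked against this package's own
    decomposition; disagreements (e.g. from pseudoknot pages) are reported as
    warnings, not errors.
    """
    path = Path(path)
    headers: dict[str, str] = {}
    body: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.rstrip("\n")
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            headers[key.strip()] = val.strip()
        elif line.strip():
            body.append(line)
    if len(body) < 3:
        raise StructureError(f"{path}: expected sequence, dot-bracket, and code lines")
    seq, db, codes = body[0].strip(), body[1].strip(), body[2].strip()
    if not re.fullmatch(r"[ACGUTNacgutn]+", seq):
        raise StructureError(f"{path}: first non-header line is not a sequence")
    if len(db) != len(seq):
        raise StructureError(f"{path}: dot-bracket length != sequence length")
    if len(codes) != len(seq) or not re.fullmatch(r"[SHBIMXEK]+", codes):
        raise StructureError(f"{path}: structure-code line missing or malformed")
    name = headers.get("Name", path.stem)
    struct = parse_dotbracket(name, seq, db)
    struct.metadata["headers"] = headers
    extra = body[3:]
    # an optional knot line (N/K per position) may precede segment lines
    if extra and re.fullmatch(r"[NK]+", extra[0]) and len(extra[0]) == len(seq):
        struct.metadata["knot_line"] = extra[0]
        extra = extra[1:]
    segments = [ln for ln in extra if _SEGMENT_RE.match(ln)]
    if segments:
        struct.metadata["segments"] = segments
        energies = {}
        for ln in segments:
            parts = ln.split()
            try:
                energies[parts[0]] = float(parts[-1])
            except ValueError:
                pass
        if energies:
            struct.metadata["energies"] = energies
    recomputed = compute_codes(struct)
    if recomputed != codes:
        diff = [i + 1 for i, (a, b) in enumerate(zip(recomputed, codes)) if a != b]
        struct.warnings.append(
            f"structure-code line disagrees with recomputed codes at positions {diff}"
        )
    struct.position_codes = recomputed
    return struct


def _segment_lines(structure: RnaStructure, sset: SubstructureSet,
                   energies: dict[str, float] | None) -> list[str]:
    seq = structure.sequence

    def subseq(lo: int, hi: int) -> str:
        return seq[lo - 1 : hi]

    def eline(label: str, body: str) -> str:
        if energies is None:
            return f"{label} {body}"
        if label in energies:
            return f"{label} {body} {energies[label]:.2f}"
        return f"{label} {body} NA"

    lines = []
    for stem in sset.stems:
        a, b = stem.strand5
        c, d = stem.strand3
        lines.append(eline(stem.label, f'{a}..{b} "{subseq(a, b)}" {c}..{d} "{subseq(c, d)}"'))
    for hp in sset.hairpins:
        lo, hi = hp.loop_positions[0], hp.loop_positions[-1]
        i, j = hp.closing_pair
        lines.append(eline(hp.label, f'{lo}..{hi} "{subseq(lo, hi)}" ({i},{j})'))
    for bl in sset.bulges:
        lo, hi = bl.bulge_positions[0], bl.bulge_positions[-1]
        lines.append(eline(bl.label, f'{lo}..{hi} "{subseq(lo, hi)}" ({bl.outer_pair[0]},{bl.outer_pair[1]}) ({bl.inner_pair[0]},{bl.inner_pair[1]})'))
    for il in sset.internal_loops:
        s5, s3 = il.side5_positions, il.side3_positions
        lines.append(
            eline(
                il.label,
                f'{s5[0]}..{s5[-1]} "{subseq(s5[0], s5[-1])}" {s3[0]}..{s3[-1]} "{subseq(s3[0], s3[-1])}"',
            )
        )
    for label, positions in sset.other_regions:
        lines.append(f'{label} {positions[0]}..{positions[-1]} "{subseq(positions[0], positions[-1])}"')
    return lines


def write_ste(structure: RnaStructure, energies, path: str | Path) -> None:
    """Write a structure-type-energy (.ste) file.

    ``energies`` is an iterable of records with ``label`` and ``dg``
    attributes (one per scored substructure, e.g. ``ComponentEnergy``), or a
    mapping label -> kcal/mol.  Every stem/hairpin/bulge/internal loop of the
    structure must have an energy record (unscorable components may carry
    ``dg=None`` and are serialized as ``NA``).
    """
    sset = decompose(structure)
    if isinstance(energies, dict):
        emap = dict(energies)
    else:
        emap = {e.label: e.dg for e in energies}
    scored_labels = [s.label for s in sset.stems] + [l.label for l in sset.loops()]
    missing = [lbl for lbl in scored_labels if lbl not in emap]
    if missing:
        raise StructureError(f"{structure.id}: no energy provided for {', '.join(missing)}")
    emap = {k: v for k, v in emap.items() if v is not None}
    headers = structure.metadata.get("headers", {})
    out = [f"#Name: {headers.get('Name', structure.id)}", f"#Length: {structure.length}"]
    for key, val in headers.items():
        if key not in ("Name", "Length"):
            out.append(f"#{key}: {val}")
    out += [structure.sequence, structure.dotbracket(), structure.position_codes]
    out += _segment_lines(structure, sset, emap)
    Path(path).write_text("\n".join(out) + "\n")


def export_hard_constraints(structure: RnaStructure) -> str:
    """Render the structure's base pairs as a hard-constraint string.

    Uses the standard folding-constraint notation consumed by constrained
    folding engines: ``(`` / ``)`` force the position to pair with its
    recorded partner, ``.`` leaves the position unconstrained.  Pseudoknot
    positions (already dropped to unpaired at parse time) are unconstrained.
    """
    return structure.dotbracket()
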