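"""Turner 2004 nearest-neighbor free energies per substructure at 37 C.

Each stem, hairpin loop, bulge, and internal loop of a decomposed structure
is scored independently, in kcal/mol, using the published Turner 2004
parameter tables (shipped with the package as plain-text assets, transcribed
from the published nearest-neighbor set; values are stored as integers in
units of 0.01 kcal/mol).

Term assignment is chosen so that, for single-branch structures, the sum of
all component energies equals the standard nearest-neighbor total (with
dangling ends disabled and multiloop/exterior contributions absent):

* stems carry their stacking terms, plus the AU/GU helix-end penalty for
  ends that face an unscored region (exterior loop or multiloop);
* hairpins carry initiation, terminal mismatch (size >= 4), special
  tri/tetra/hexaloop energies, and the AU/GU closure penalty of triloops;
* bulges of size 1 carry the through-bulge stacking term; larger bulges
  carry the AU/GU penalties of both closing pairs;
* internal loops carry initiation, asymmetry (Ninio), and their terminal
  mismatch terms (1x1, 2x1, and 2x2 loops are exact table lookups).

Multiloop and exterior-loop terms are never computed.  Components touching
non-canonical pairs, ambiguous bases (N), or hairpins of size < 3 are marked
unscorable rather than guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structures import (
    Bulge,
    HairpinLoop,
    InternalLoop,
    RnaStructure,
    Stem,
    SubstructureSet,
    decompose,
)

__all__ = [
    "TurnerParameters",
    "ComponentEnergy",
    "ParameterError",
    "load_turner_params",
    "stem_dg",
    "hairpin_dg",
    "bulge_dg",
    "internal_dg",
    "annotate_structure_energies",
    "total_single_branch_dg",
]

DATA_DIR = Path(__file__).parent / "data" / "turner2004"

# base encoding: N=0, A=1, C=2, G=3, U=4 (table row/column order)
_BASE = {"N": 0, "A": 1, "C": 2, "G": 3, "U": 4}
# pair-type encoding over the canonical pairs (table page order); index 6 = NN
_PAIR = {
    ("C", "G"): 0,
    ("G", "C"): 1,
    ("G", "U"): 2,
    ("U", "G"): 3,
    ("A", "U"): 4,
    ("U", "A"): 5,
}
#: pair types carrying the AU/GU helix-end penalty
_WEAK_TYPES = frozenset({2, 3, 4, 5})

MAX_TABULATED_LOOP = 30


class ParameterError(ValueError):
    """Raised when a parameter table is missing or malformed."""


@dataclass
class TurnerParameters:
    """Turner 2004 dG tables at 37 C, all values kcal/mol * 100 (int)."""

    stack: np.ndarray  # (7, 7)
    mismatch_hairpin: np.ndarray  # (7, 5, 5)
    mismatch_internal: np.ndarray
    mismatch_internal_1n: np.ndarray
    mismatch_internal_23: np.ndarray
    int11: np.ndarray  # (7, 7, 5, 5)
    int21: np.ndarray  # (7, 7, 5, 5, 5)
    int22: np.ndarray  # (6, 6, 4, 4, 4, 4)
    hairpin_init: np.ndarray  # (31,) sizes 0..30
    bulge_init: np.ndarray
    internal_init: np.ndarray
    special_hairpins: dict[str, int]
    ninio_m: int
    ninio_max: int
    au_end_penalty: int
    jacobson_coeff: float  # 1.75 * R * T at 310.15 K, in 0.01 kcal/mol
    temperature: float = 37.0

    def pair_type(self, b5: str, b3: str) -> int | None:
        """Pair-type index of the 5'->3' pair (b5, b3); None if non-canonical."""
        return _PAIR.get((b5, b3))


def _read_values(path: Path) -> list[int]:
    vals: list[int] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            continue
        vals.extend(int(tok) for tok in line.split())
    return vals


def _load_array(path: Path, shape: tuple[int, ...]) -> np.ndarray:
    vals = _read_values(path)
    expected = int(np.prod(shape))
    if len(vals) != expected:
        raise ParameterError(
            f"{path.name}: expected {expected} values for shape {shape}, got {len(vals)}"
        )
    return np.array(vals, dtype=np.int64).reshape(shape)


def load_turner_params(path: str | Path | None = None) -> TurnerParameters:
    """Load the packaged Turner 2004 tables (or another directory of the
    same dialect).

    Raises :class:`ParameterError` naming the missing table if a file is
    absent or the wrong size.
    """
    base = Path(path) if path is not None else DATA_DIR
    required = {
        "stack": (7, 7),
        "mismatch_hairpin": (7, 5, 5),
        "mismatch_internal": (7, 5, 5),
        "mismatch_internal_1n": (7, 5, 5),
        "mismatch_internal_23": (7, 5, 5),
        "int11": (7, 7, 5, 5),
        "int21": (7, 7, 5, 5, 5),
        "int22": (6, 6, 4, 4, 4, 4),
    }
    arrays = {}
    for name, shape in required.items():
        f = base / f"{name}.txt"
        if not f.exists():
            raise ParameterError(f"{name} table absent from {base}")
        arrays[name] = _load_array(f, shape)
    loops_f = base / "loop_init.txt"
    if not loops_f.exists():
        raise ParameterError(f"loop initiation table absent from {base}")
    loops = _load_array(loops_f, (3, 31))
    misc_f = base / "misc.txt"
    if not misc_f.exists():
        raise ParameterError(f"misc table absent from {base}")
    misc: dict[str, float] = {}
    for line in misc_f.read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        key, val = line.split()
        misc[key] = float(val)
    special_f = base / "special_hairpins.txt"
    if not special_f.exists():
        raise ParameterError(f"special hairpin table absent from {base}")
    special: dict[str, int] = {}
    for line in special_f.read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        seq, val = line.split()
        special[seq] = int(val)
    return TurnerParameters(
        **arrays,
        hairpin_init=loops[0],
        bulge_init=loops[1],
        internal_init=loops[2],
        special_hairpins=special,
        ninio_m=int(misc["ninio"]),
        ninio_max=int(misc["ninio_max"]),
        au_end_penalty=int(misc["terminal_au"]),
        jacobson_coeff=misc["lxc"],
    )


@dataclass
class ComponentEnergy:
    """Free energy of one substructure with a named term breakdown.

    ``dg`` is in kcal/mol; ``None`` means the component is unscorable (see
    ``reason``).  ``dg`` always equals the sum of ``terms`` values.
    """

    label: str
    kind: str  # stem | hairpin | bulge | internal
    dg: float | None
    terms: dict[str, float] = field(default_factory=dict)
    reason: str | None = None

    @property
    def scorable(self) -> bool:
        return self.dg is not None


def _unscorable(label: str, kind: str, reason: str) -> ComponentEnergy:
    return ComponentEnergy(label=label, kind=kind, dg=None, reason=reason)


def _finish(label: str, kind: str, terms: dict[str, int]) -> ComponentEnergy:
    terms_kcal = {k: round(v) / 100.0 for k, v in terms.items()}
    return ComponentEnergy(
        label=label, kind=kind, dg=round(sum(terms.values())) / 100.0, terms=terms_kcal
    )


def _loop_init(table: np.ndarray, size: int, params: TurnerParameters) -> int:
    """Tabulated initiation, Jacobson-Stockmayer extrapolated past size 30."""
    if size <= MAX_TABULATED_LOOP:
        return int(table[size])
    # truncation (not rounding) of the log term matches the published
    # integer-valued tables' convention
    return int(table[MAX_TABULATED_LOOP]) + int(
        params.jacobson_coeff * math.log(size / MAX_TABULATED_LOOP)
    )


def stem_dg(
    stem: Stem,
    sequence: str,
    params: TurnerParameters,
    *,
    end_penalties: tuple[bool, bool] = (False, False),
) -> ComponentEnergy:
    """Stacking free energy of a helix.

    ``end_penalties`` selects whether the AU/GU helix-end penalty is charged
    at the (outer, inner) terminal pair; :func:`annotate_structure_energies`
    sets these from structural context so that penalties facing scored loops
    stay with the loop component.  A length-1 stem has no stacking terms.
    """
    types = []
    for i, j in stem.pairs:
        t = params.pair_type(sequence[i - 1], sequence[j - 1])
        if t is None:
            return _unscorable(
                stem.label, "stem",
                f"non-canonical pair {sequence[i - 1]}{i}:{sequence[j - 1]}{j}",
            )
        types.append(t)
    stack_total = 0
    for k in range(len(stem.pairs) - 1):
        i2, j2 = stem.pairs[k + 1]
        t_rev = params.pair_type(sequence[j2 - 1], sequence[i2 - 1])
        stack_total += int(params.stack[types[k], t_rev])
    terms: dict[str, int] = {"stacks": stack_total}
    penalty = 0
    for charge, t in zip(end_penalties, (types[0], types[-1])):
        if charge and t in _WEAK_TYPES:
            penalty += params.au_end_penalty
    if penalty:
        terms["end_penalty"] = penalty
    return _finish(stem.label, "stem", terms)


def hairpin_dg(h: HairpinLoop, sequence: str, params: TurnerParameters) -> ComponentEnergy:
    """Hairpin loop free energy (Turner 2004 rules).

    Size >= 3 required.  The full closing-pair + loop string is checked
    against the special tri/tetra/hexaloop table first; otherwise
    initiation(size), plus the terminal mismatch for size >= 4 or the AU/GU
    closure penalty for size 3.  Sizes > 30 use the Jacobson-Stockmayer
    log extrapolation.
    """
    i, j = h.closing_pair
    size = h.size
    if size < 3:
        return _unscorable(h.label, "hairpin", f"hairpin size {size} < 3")
    loop_str = sequence[i - 1 : j]  # closing 5' base .. closing 3' base
    if "N" in loop_str:
        return _unscorable(h.label, "hairpin", "ambiguous base in loop context")
    t = params.pair_type(sequence[i - 1], sequence[j - 1])
    if t is None:
        return _unscorable(h.label, "hairpin", "non-canonical closing pair")
    if size in (3, 4, 6) and loop_str in params.special_hairpins:
        return _finish(
            h.label, "hairpin", {"special": params.special_hairpins[loop_str]}
        )
    terms: dict[str, int] = {"initiation": _loop_init(params.hairpin_init, size, params)}
    if size == 3:
        if t in _WEAK_TYPES:
            terms["end_penalty"] = params.au_end_penalty
    else:
        si1 = _BASE[sequence[i]]
        sj1 = _BASE[sequence[j - 2]]
        terms["mismatch"] = int(params.mismatch_hairpin[t, si1, sj1])
    return _finish(h.label, "hairpin", terms)


def bulge_dg(b: Bulge, sequence: str, params: TurnerParameters) -> ComponentEnergy:
    """Bulge loop free energy.

    Size 1: initiation(1) plus the stacking of the closing pairs across the
    bulge (the helix is treated as stacking through).  Size >= 2: initiation
    plus the AU/GU penalty for each closing pair.  Sizes > 30 extrapolated.
    """
    (i, j), (k, l) = b.outer_pair, b.inner_pair
    t_out = params.pair_type(sequence[i - 1], sequence[j - 1])
    t_in_rev = params.pair_type(sequence[l - 1], sequence[k - 1])
    if t_out is None or t_in_rev is None:
        return _unscorable(b.label, "bulge", "non-canonical closing pair")
    if any(sequence[p - 1] == "N" for p in b.bulge_positions):
        return _unscorable(b.label, "bulge", "ambiguous base in bulge")
    size = b.size
    terms: dict[str, int] = {"initiation": _loop_init(params.bulge_init, size, params)}
    if size == 1:
        terms["through_stack"] = int(params.stack[t_out, t_in_rev])
    else:
        penalty = 0
        for t in (t_out, t_in_rev):
            if t in _WEAK_TYPES:
                penalty += params.au_end_penalty
        if penalty:
            terms["end_penalty"] = penalty
    return _finish(b.label, "bulge", terms)


def internal_dg(il: InternalLoop, sequence: str, params: TurnerParameters) -> ComponentEnergy:
    """Internal loop free energy.

    1x1, 2x1/1x2, and 2x2 loops are exact table lookups; 2x3/3x2 and 1xn
    loops use their dedicated mismatch tables; all other sizes use the
    generic initiation + Ninio asymmetry + terminal mismatch rules.
    """
    (i, j), (k, l) = il.outer_pair, il.inner_pair
    n1, n2 = il.sizes
    t1 = params.pair_type(sequence[i - 1], sequence[j - 1])
    t2 = params.pair_type(sequence[l - 1], sequence[k - 1])  # inner pair, reversed
    if t1 is None or t2 is None:
        return _unscorable(il.label, "internal", "non-canonical closing pair")
    context = sequence[i - 1 : k] + sequence[l - 1 : j]
    if "N" in context:
        return _unscorable(il.label, "internal", "ambiguous base in loop context")
    si1 = _BASE[sequence[i]]      # 5' of loop, after outer pair
    sj1 = _BASE[sequence[j - 2]]  # 3' of loop, before outer pair
    sp1 = _BASE[sequence[k - 2]]  # before inner pair on 5' strand
    sq1 = _BASE[sequence[l]]      # after inner pair on 3' strand
    ns, nl = min(n1, n2), max(n1, n2)
    if ns == 1 and nl == 1:
        return _finish(il.label, "internal", {"int11": int(params.int11[t1, t2, si1, sj1])})
    if ns == 1 and nl == 2:
        if n1 == 1:
            val = int(params.int21[t1, t2, si1, sq1, sj1])
        else:
            val = int(params.int21[t2, t1, sq1, si1, sp1])
        return _finish(il.label, "internal", {"int21": val})
    if ns == 2 and nl == 2:
        return _finish(
            il.label,
            "internal",
            {"int22": int(params.int22[t1, t2, si1 - 1, sp1 - 1, sq1 - 1, sj1 - 1])},
        )
    terms: dict[str, int] = {}
    if ns == 2 and nl == 3:
        terms["initiation"] = _loop_init(params.internal_init, 5, params)
        terms["asymmetry"] = min(params.ninio_max, params.ninio_m)
        mm = params.mismatch_internal_23
    elif ns == 1:
        terms["initiation"] = _loop_init(params.internal_init, 1 + nl, params)
        terms["asymmetry"] = min(params.ninio_max, (nl - 1) * params.ninio_m)
        mm = params.mismatch_internal_1n
    else:
        terms["initiation"] = _loop_init(params.internal_init, n1 + n2, params)
        terms["asymmetry"] = min(params.ninio_max, abs(n1 - n2) * params.ninio_m)
        mm = params.mismatch_internal
    terms["mismatch"] = int(mm[t1, si1, sj1]) + int(mm[t2, sq1, sp1])
    if terms["asymmetry"] == 0:
        del terms["asymmetry"]
    return _finish(il.label, "internal", terms)


def annotate_structure_energies(
    structure: RnaStructure,
    params: TurnerParameters,
    sset: SubstructureSet | None = None,
) -> list[ComponentEnergy]:
    """Score every stem, hairpin, bulge, and internal loop of a structure.

    Multiloop and external regions yield no record.  Unscorable components
    are returned with ``dg=None`` (never silently dropped), so callers can
    report them from the same list.
    """
    if sset is None:
        sset = decompose(structure)
    seq = structure.sequence
    # Each terminal pair of a stem faces one loop on its outward side; the
    # AU/GU penalty for that side belongs to the facing loop when the loop is
    # a scored component, and to the stem when it faces an unscored region
    # (exterior or multiloop).  A length-1 stem has two outward sides.
    above_owned: set[tuple[int, int]] = set()  # pair's enclosing loop is scored
    below_owned: set[tuple[int, int]] = set()  # pair's enclosed loop is scored
    for hp in sset.hairpins:
        below_owned.add(hp.closing_pair)
    for two_way in (*sset.bulges, *sset.internal_loops):
        below_owned.add(two_way.outer_pair)
        above_owned.add(two_way.inner_pair)
    out: list[ComponentEnergy] = []
    for stem in sset.stems:
        outer_free = stem.pairs[0] not in above_owned
        inner_free = stem.pairs[-1] not in below_owned
        out.append(stem_dg(stem, seq, params, end_penalties=(outer_free, inner_free)))
    for hp in sset.hairpins:
        out.append(hairpin_dg(hp, seq, params))
    for b in sset.bulges:
        out.append(bulge_dg(b, seq, params))
    for il in sset.internal_loops:
        out.append(internal_dg(il, seq, params))
    return out


def total_single_branch_dg(structure: RnaStructure, params: TurnerParameters) -> float:
    """Sum of component energies for a single-branch structure, kcal/mol.

    Defined only for structures without multiloops (every loop is a hairpin,
    bulge, or internal loop); raises otherwise, and raises if any component
    is unscorable.
    """
    sset = decompose(structure)
    if any(lbl.startswith("M") for lbl, _ in sset.other_regions):
        raise ValueError(f"{structure.id}: total energy undefined for multibranch structures")
    energies = annotate_structure_energies(structure, params, sset)
    bad = [e for e in energies if not e.scorable]
    if bad:
        raise ValueError(
            f"{structure.id}: unscorable components: "
            + "; ".join(f"{e.label} ({e.reason})" for e in bad)
        )
    return round(sum(e.dg for e in energies), 10)
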