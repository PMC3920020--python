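"""Secondary-structure representation and hairpin analytics.

Terminology used throughout (the field's usage is loose, so the contracts
here are explicit):

* mismatch  -- a symmetric 1:1 internal loop (one unpaired base opposing one
  unpaired base inside a stem);
* bulge     -- an unpaired run on one strand only (for an asymmetric internal
  loop, the size asymmetry is scored as a bulge and the symmetric part as
  mismatches);
* core region -- the stem segment whose residues align with the mature small
  RNA read;
* miRNA*    -- the opposite-arm strand of the mature/star duplex, carrying
  the canonical 2-nt 3' overhang on both strands.

G:U is a legal structural pair here; in target alignment (targets module)
it counts as a mismatch. The two contracts are intentionally different.

Internally all coordinates are 0-based and spans half-open; report layers
convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import fold as _fold
from .model import to_rna

LEGAL_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


class StructureError(ValueError):
    pass


@dataclass
class PairTable:
    """A parsed secondary structure: sequence, dot-bracket, partner map, MFE.

    ``partner[i]`` is the 0-based paired position or None. The invariants
    (symmetry, involution, pair legality, nesting) are checked on build.
    ``backend`` tags which folding engine produced the MFE -- energies from
    different backends are not comparable and must never be mixed when a
    threshold (e.g. the MFE prediction interval) is trained and applied.
    """

    sequence: str
    dotbracket: str
    partner: list
    mfe: float
    fold_temperature: float = 25.0
    backend: str = "builtin"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if len(self.dotbracket) != n or len(self.partner) != n:
            raise StructureError("sequence/structure length mismatch")
        for i, j in enumerate(self.partner):
            if j is None:
                continue
            if self.partner[j] != i:
                raise StructureError(f"partner map not involutive at {i}")
            if i < j:
                pair = (self.sequence[i], self.sequence[j])
                if pair not in LEGAL_PAIRS:
                    raise StructureError(
                        f"illegal pair {pair[0]}:{pair[1]} at positions {i + 1},{j + 1}"
                    )
        # nesting (no pseudoknots): bracket matching must reproduce partners
        stack = []
        for i, c in enumerate(self.dotbracket):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise StructureError("unbalanced dot-bracket")
                j = stack.pop()
                if self.partner[i] != j:
                    raise StructureError("partner map is pseudoknotted or inconsistent")
        if stack:
            raise StructureError("unbalanced dot-bracket")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_pairs(self) -> int:
        return sum(1 for j in self.partner if j is not None) // 2

    def pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in enumerate(self.partner) if j is not None and i < j]


def render_dotbracket(partner: list) -> str:
    out = []
    for i, j in enumerate(partner):
        if j is None:
            out.append(".")
        else:
            out.append("(" if i < j else ")")
    return "".join(out)


def parse_dotbracket(sequence: str, dotbracket: str, mfe: float = 0.0,
                     temperature: float = 25.0, backend: str = "external") -> PairTable:
    """Build a PairTable by stack-matching a Vienna-style dot-bracket string."""
    seq = to_rna(sequence)
    if len(seq) != len(dotbracket):
        raise StructureError("sequence/structure length mismatch")
    partner: list = [None] * len(seq)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced dot-bracket at position {i + 1}")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise StructureError(f"illegal character {c!r} at position {i + 1}")
    if stack:
        raise StructureError(f"unbalanced dot-bracket: unmatched '(' at position {stack[-1] + 1}")
    return PairTable(sequence=seq, dotbracket=dotbracket, partner=partner,
                     mfe=mfe, fold_temperature=temperature, backend=backend)


def fold(sequence: str, temperature: float = 25.0, backend: str = "builtin",
         structure_file=None) -> PairTable:
    """Fold a sequence into a PairTable.

    backend="builtin" runs the packaged stacking-model optimiser (the
    temperature is recorded but does not enter the simplified model);
    backend="external-file" parses a Vienna-style structure file produced by
    any folding program (header, sequence, dot-bracket with trailing
    "(MFE)").
    """
    if len(sequence) < 10 and backend == "builtin":
        # folding still works; guard only against nonsense input
        pass
    if backend == "builtin":
        partner, mfe = _fold.fold_builtin(sequence)
        return PairTable(sequence=to_rna(sequence), dotbracket=render_dotbracket(partner),
                         partner=partner, mfe=mfe, fold_temperature=temperature,
                         backend="builtin")
    if backend == "external-file":
        if structure_file is None:
            raise StructureError("external-file backend requires structure_file")
        return read_vienna(structure_file)
    raise StructureError(f"unknown folding backend {backend!r}")


def read_vienna(path) -> PairTable:
    """Read a 3-line Vienna file: >header / sequence / structure (MFE)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3 or not lines[0].startswith(">"):
        raise StructureError(f"unreadable structure file {path}")
    seq = lines[1]
    struct_line = lines[2]
    mfe = 0.0
    if "(" in struct_line and struct_line.rstrip().endswith(")"):
        # trailing "(-12.3)" energy annotation
        idx = struct_line.rfind(" (")
        if idx > 0:
            try:
                mfe = float(struct_line[idx + 2:].rstrip(")").strip())
                struct_line = struct_line[:idx].strip()
            except ValueError:
                pass
    return parse_dotbracket(seq, struct_line, mfe=mfe, backend="external-file")


def write_vienna(pt: PairTable, path, header: str = "structure") -> None:
    Path(path).write_text(f">{header}\n{pt.sequence}\n{pt.dotbracket} ({pt.mfe:.2f})\n")


# ---------------------------------------------------------------------------
# hairpin metrics


@dataclass
class HairpinMetrics:
    terminal_loop_size: int
    branch_count: int
    loop_count: int
    stems: list = field(default_factory=list)        # (start5, end5, start3, end3) 0-based
    bulges: list = field(default_factory=list)       # (side, start, size)
    mismatch_positions: list = field(default_factory=list)


def _children(pt: PairTable, i: int, j: int) -> list[tuple[int, int]]:
    """Maximal pairs strictly inside (i, j) (or inside the whole sequence if
    i, j delimit the exterior)."""
    out = []
    p = i + 1
    while p < j:
        q = pt.partner[p]
        if q is not None and q > p:
            out.append((p, q))
            p = q + 1
        else:
            p += 1
    return out


def _subtended_pairs(pt: PairTable, i: int, j: int) -> int:
    return sum(1 for p in range(i, j + 1) if pt.partner[p] is not None) // 2


def hairpin_metrics(pt: PairTable) -> HairpinMetrics:
    """Stem/loop/bulge/branch census of a structure.

    * terminal loop: the hairpin loop reached by walking the main stem from
      the outermost pair, taking the pair-richest branch at any multiloop;
    * branch_count: helices emanating from multiloops beyond the entering
      helix, summed over all multiloops (the exterior counts when it holds
      more than one helix);
    * bulges/mismatches: see module docstring.
    """
    n = len(pt)
    top = _children(pt, -1, n)
    if not top:
        return HairpinMetrics(terminal_loop_size=0, branch_count=0, loop_count=0)

    stems: list[tuple[int, int, int, int]] = []
    bulges: list[tuple[str, int, int]] = []
    mismatches: list[tuple[int, int]] = []
    loop_count = 0
    branch_count = len(top) if len(top) > 1 else 0

    # stems: maximal runs of strictly stacked pairs
    seen = set()
    for i, j in pt.pairs():
        if (i, j) in seen:
            continue
        outer_stacked = i - 1 >= 0 and j + 1 < n and pt.partner[i - 1] == j + 1
        if outer_stacked:
            continue  # not the outer end of its helix
        s5, e5, s3, e3 = i, i, j, j
        while (e5 + 1 < s3 - 1 and pt.partner[e5 + 1] == s3 - 1):
            e5 += 1
            s3 -= 1
            seen.add((e5, s3))
        stems.append((s5, e5, s3, e3))

    # loop classification via tree traversal
    stack = list(top)
    while stack:
        i, j = stack.pop()
        kids = _children(pt, i, j)
        if not kids:
            loop_count += 1
        elif len(kids) == 1:
            (ci, cj) = kids[0]
            left = ci - i - 1
            right = j - cj - 1
            if left or right:
                if left == right == 1:
                    mismatches.append((i + 1, j - 1))
                elif left and not right:
                    bulges.append(("5p", i + 1, left))
                elif right and not left:
                    bulges.append(("3p", cj + 1, right))
                else:
                    # asymmetric internal loop: symmetric part as mismatches,
                    # the excess as a bulge on the longer side
                    for k in range(min(left, right)):
                        mismatches.append((i + 1 + k, j - 1 - k))
                    if left > right:
                        bulges.append(("5p", i + 1 + right, left - right))
                    else:
                        bulges.append(("3p", cj + 1 + left, right - left))
            stack.append(kids[0])
        else:
            branch_count += len(kids)
            stack.extend(kids)

    # terminal loop: walk the pair-richest path from the pair-richest top helix
    i, j = max(top, key=lambda ij: _subtended_pairs(pt, *ij))
    while True:
        kids = _children(pt, i, j)
        if not kids:
            terminal = j - i - 1
            break
        i, j = max(kids, key=lambda ij: _subtended_pairs(pt, *ij))

    return HairpinMetrics(terminal_loop_size=terminal, branch_count=branch_count,
                          loop_count=loop_count, stems=stems, bulges=bulges,
                          mismatch_positions=mismatches)


# ---------------------------------------------------------------------------
# core region


@dataclass
class CoreRegion:
    span: tuple[int, int]            # 0-based half-open mature footprint
    length_bp: int                   # paired residues within the span
    bulge_count: int
    max_bulge_size: int
    max_continuous_unpaired: int
    unpaired_count: int              # unpaired mature-span residues
    contains_loop_or_branch: bool


class CoreRejection(Exception):
    """Raised when the mature read does not sit in the stem of the hairpin."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def _enclosing_pair(pt: PairTable, p: int) -> tuple[int, int] | None:
    """Innermost pair (i, j) with i < p < j, or None if p is exterior."""
    depth = 0
    for i in range(p - 1, -1, -1):
        j = pt.partner[i]
        if j is None:
            continue
        if j < i:          # a closed pair entirely left of p
            depth += 1
        else:              # an opening bracket; unmatched ones enclose p
            if depth == 0:
                return (i, j)
            depth -= 1
    return None


def locate_core(pt: PairTable, mature_span: tuple[int, int]) -> CoreRegion:
    """Evaluate the mature footprint on the folded structure.

    Rejects (CoreRejection) when any mature residue lies in a hairpin
    (terminal) loop or outside the folded stem entirely. Multiloop exposure
    is not a rejection here -- it sets ``contains_loop_or_branch`` and the
    precursor filter decides.
    """
    s, e = mature_span
    if s < 0 or e > len(pt) or s >= e:
        raise ValueError("mature span outside sequence")
    contains_loop_or_branch = False
    for p in range(s, e):
        if pt.partner[p] is not None:
            continue
        enc = _enclosing_pair(pt, p)
        if enc is None:
            raise CoreRejection("in_loop")  # dangling outside the stem
        kids = _children(pt, *enc)
        if not kids:
            raise CoreRejection("in_loop")  # hairpin/terminal loop
        if len(kids) > 1:
            contains_loop_or_branch = True  # multiloop exposure

    paired = [p for p in range(s, e) if pt.partner[p] is not None]
    if not paired:
        raise CoreRejection("in_loop")
    # partner positions must run monotonically (single arm, no loop crossing)
    partners = [pt.partner[p] for p in paired]
    mono_dec = all(b < a for a, b in zip(partners, partners[1:]))
    mono_inc = all(b > a for a, b in zip(partners, partners[1:]))
    if not (mono_dec or mono_inc):
        contains_loop_or_branch = True

    length_bp = len(paired)
    bulge_count = 0
    max_bulge = 0
    mismatch_unpaired = 0
    for a, b in zip(paired, paired[1:]):
        g5 = b - a - 1
        pa, pb = pt.partner[a], pt.partner[b]
        g3 = abs(pa - pb) - 1
        # a helix between the two partner positions is a branch inside the core
        lo, hi = sorted((pa, pb))
        if any(pt.partner[q] is not None for q in range(lo + 1, hi)):
            contains_loop_or_branch = True
        if g5 == 0 and g3 == 0:
            continue
        if g5 == g3 == 1:
            mismatch_unpaired += 1
            continue
        sym = min(g5, g3)
        mismatch_unpaired += sym if sym == g5 else sym  # symmetric part
        excess = abs(g5 - g3)
        if excess:
            bulge_count += 1
            max_bulge = max(max_bulge, excess)

    # unpaired mature residues, incl. duplex-end overhangs within the span
    unpaired_flags = [pt.partner[p] is None for p in range(s, e)]
    unpaired_count = sum(unpaired_flags)
    max_run = run = 0
    for f in unpaired_flags:
        run = run + 1 if f else 0
        max_run = max(max_run, run)

    return CoreRegion(span=(s, e), length_bp=length_bp, bulge_count=bulge_count,
                      max_bulge_size=max_bulge, max_continuous_unpaired=max_run,
                      unpaired_count=unpaired_count,
                      contains_loop_or_branch=contains_loop_or_branch)


# ---------------------------------------------------------------------------
# miRNA* derivation and precursor trimming


@dataclass
class Duplex:
    mature: tuple[int, int]   # 0-based half-open
    star: tuple[int, int]
    overhang_3prime: int = 2


class NoDuplexError(Exception):
    pass


def _resolve_partner(pt: PairTable, q: int) -> int | None:
    """Partner of q, or of the nearest paired neighbour with positional
    compensation (moving d bases along one arm moves the partner -d)."""
    if 0 <= q < len(pt) and pt.partner[q] is not None:
        return pt.partner[q]
    for d in range(1, len(pt)):
        for q2 in (q + d, q - d):
            if 0 <= q2 < len(pt) and pt.partner[q2] is not None:
                comp = pt.partner[q2] + (q2 - q)
                if 0 <= comp < len(pt):
                    return comp
                return None
    return None


def derive_star(pt: PairTable, mature_span: tuple[int, int]) -> Duplex:
    """Derive the miRNA* span from the pair table.

    With the mature at closed positions [s, e] the star runs from
    partner(e-2) to partner(s)+2: base-pairing partners shifted to give the
    canonical 2-nt 3' overhang on both strands. Unpaired anchor positions
    are resolved via the nearest paired neighbour.
    """
    s, e_open = mature_span
    e = e_open - 1  # closed end
    n_paired = sum(1 for p in range(s, e_open) if pt.partner[p] is not None)
    if n_paired < (e_open - s) // 2:
        raise NoDuplexError("mature arm cannot form a duplex (too few partners)")
    lo_anchor = _resolve_partner(pt, e - 2)
    hi_anchor = _resolve_partner(pt, s)
    if lo_anchor is None or hi_anchor is None:
        raise NoDuplexError("mature arm cannot form a duplex (too few partners)")
    star_lo, star_hi = lo_anchor, hi_anchor + 2
    star_lo = max(0, star_lo)
    star_hi = min(len(pt) - 1, star_hi)
    if star_hi <= star_lo:
        raise NoDuplexError("degenerate star span")
    star = (star_lo, star_hi + 1)
    if not (star[1] <= s or star[0] >= e_open):
        raise NoDuplexError("star span overlaps the mature span")
    return Duplex(mature=(s, e_open), star=star)


def star_sequence(pt: PairTable, duplex: Duplex) -> str:
    """Star strand read 5'->3' (the stored sequence already is 5'->3')."""
    lo, hi = duplex.star
    return pt.sequence[lo:hi]


@dataclass
class TrimResult:
    sequence: str
    pair_table: PairTable
    offset: int  # trim start in original coordinates


def trim_precursor(pt: PairTable, duplex: Duplex, flank: int = 10) -> TrimResult:
    """Trim the candidate to the duplex plus ``flank`` nt outside the
    terminal mature/miRNA* base pair, then refold.

    The kept region is [outermost duplex pair 5' position - flank,
    outermost pair 3' position + flank], clamped to the sequence.
    """
    ms, me = duplex.mature
    ss, se = duplex.star
    pairs = [(p, pt.partner[p]) for p in range(ms, me)
             if pt.partner[p] is not None and ss <= pt.partner[p] < se]
    if not pairs:
        raise NoDuplexError("no base pair between mature and star")
    lo = min(min(p, q) for p, q in pairs)
    hi = max(max(p, q) for p, q in pairs)
    start = max(0, lo - flank)
    end = min(len(pt), hi + flank + 1)
    sub = pt.sequence[start:end]
    # refolding always uses the builtin engine; an external-file structure
    # cannot be re-queried, and mixing backends would corrupt MFE filters
    refolded = fold(sub, temperature=pt.fold_temperature, backend="builtin")
    return TrimResult(sequence=sub, pair_table=refolded, offset=start)
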