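"""Nearest-neighbor free-energy model and minimum-free-energy hybridization.

The duplex engine finds the minimum-free-energy *intermolecular* structure
of two short RNAs: stacked pairs, bulges and internal loops only — no
intramolecular pairs and no multi-branch loops, the approximation used by
miRNA-target style hybridization tools.  Watson-Crick and G:U pairs are
allowed.  Helix ends collect dangling-end contributions from both strands;
a helix end with no dangling neighbor on either strand pays a small
blunt-end term.  There is no duplex-initiation or terminal-AU term in the
duplex model: the shipped Turner-1999-style tables are calibrated so that
hybridizing the four SD tetramers (AAGG, AGGA, GGAG, GAGG) against the
canonical anti-SD tail reproduces the reference energies -7.1, -8.0,
-9.3 and -9.1 kcal/mol, whose mean gives the -8.4 kcal/mol SD threshold.

All energies are handled internally as integer centi-kcal (0.01 kcal/mol)
so that comparisons and tie-breaking are exact; public APIs speak kcal/mol.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterTableError

logger = logging.getLogger(__name__)

INF = 10**9

#: tables are indexed by pair type in this order
PAIR_ORDER = ("CG", "GC", "GU", "UG", "AU", "UA")
BASES = "NACGU"
_B = {c: i for i, c in enumerate(BASES)}

#: the canonical (E. coli-type) 16S 3' unstructured tail, 5'->3'.  The
#: CCUCC core sits at positions 7-11 (0-based); its central U (index 9) is
#: position 0 of the anti-SD coordinate system.  This sequence is the
#: calibration target for the SD tetramer energies: the bases flanking the
#: CCUCCUU core contribute the dangling-end terms of the reference values.
CANONICAL_TAIL = "UGGAUCACCUCCUUA"

#: the four SD tetramers complementary to a 4-mer of the CCUCCUU core
SD_TETRAMERS = ("AAGG", "AGGA", "GGAG", "GAGG")

# pair-type lookup: PT[a][b] = index into PAIR_ORDER, or -1
PT = np.full((5, 5), -1, dtype=np.int8)
for _k, (_x, _y) in enumerate(PAIR_ORDER):
    PT[_B[_x], _B[_y]] = _k


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as uint8 (N,A,C,G,U -> 0..4); any non-ACGU
    character becomes N and is unpairable."""
    return np.array([_B.get(c, 0) for c in seq], dtype=np.uint8)


@dataclass
class LoopLimits:
    """Maximum unpaired stretch per strand inside a duplex loop."""

    max_bulge: int = 15
    max_internal: int = 15


@dataclass
class EnergyModel:
    """Nearest-neighbor parameter set (integer centi-kcal/mol)."""

    stack: np.ndarray          # (6, 6): stack[outer][inner reversed]
    dangle5: np.ndarray        # (6, 5): [pair][dangling base], col 0 = N
    dangle3: np.ndarray        # (6, 5)
    hairpin: np.ndarray        # (31,): size-indexed, sizes < 3 invalid
    bulge: np.ndarray          # (31,)
    internal: np.ndarray       # (31,)
    ninio_m: int = 50
    ninio_max: int = 300
    lxc: float = 107.856
    terminal_au: int = 50      # folding engine only (AU/GU helix ends)
    helix_end_blunt: int = 45  # per dangle-less duplex helix end
    duplex_init: int = 0
    source: str = "builtin"

    @property
    def allowed_pairs(self) -> set[str]:
        return set(PAIR_ORDER)

    def pair_type(self, a: str, b: str) -> int:
        return int(PT[_B.get(a, 0), _B.get(b, 0)])

    def loop_size_penalty(self, table: np.ndarray, size: int) -> int:
        """Length penalty with logarithmic extrapolation beyond size 30."""
        if size <= 30:
            v = int(table[size])
            if v >= INF:
                raise ParameterTableError(f"loop size {size} not allowed")
            return v
        return int(table[30] + round(self.lxc * math.log(size / 30.0)))

    def checksum(self) -> str:
        h = hashlib.sha256()
        for arr in (self.stack, self.dangle5, self.dangle3,
                    self.hairpin, self.bulge, self.internal):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(
            f"{self.ninio_m},{self.ninio_max},{self.lxc},"
            f"{self.terminal_au},{self.helix_end_blunt},{self.duplex_init}".encode()
        )
        return h.hexdigest()[:16]


def _parse_blocks(text: str) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    cur = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            cur = line[1:-1]
            blocks[cur] = []
        elif cur is not None:
            blocks[cur].extend(line.split())
    return blocks


def _table(blocks, name, shape, fill=0) -> np.ndarray:
    if name not in blocks:
        logger.warning("parameter file: missing [%s]; defaulting to %d", name, fill)
        return np.full(shape, fill, dtype=np.int32)
    vals = blocks[name]
    try:
        arr = np.array([int(v) for v in vals], dtype=np.int32)
    except ValueError as exc:
        raise ParameterTableError(f"[{name}]: non-integer entry ({exc})") from exc
    if arr.size != int(np.prod(shape)):
        raise ParameterTableError(
            f"[{name}]: expected {int(np.prod(shape))} values, got {arr.size}"
        )
    return arr.reshape(shape)


def load_energy_model(path=None) -> EnergyModel:
    """Load the nearest-neighbor tables (shipped defaults when no path).

    Missing dangle tables default to zeros with a warning; the sha256
    checksum of the loaded tables is logged.
    """
    if path is None:
        text = (
            resources.files("antisdscan.data")
            .joinpath("rna_nn_params.txt")
            .read_text()
        )
        src = "builtin:rna_nn_params.txt"
    else:
        with open(path) as fh:
            text = fh.read()
        src = str(path)
    blocks = _parse_blocks(text)
    if "stack" not in blocks:
        raise ParameterTableError("parameter file: missing [stack] block")
    stack = _table(blocks, "stack", (6, 6))

    def dangle(name):
        d = np.zeros((6, 5), dtype=np.int32)
        d[:, 1:] = _table(blocks, name, (6, 4))
        return d

    def loop(name, first):
        t = np.full(31, INF, dtype=np.int32)
        vals = _table(blocks, name, (31 - first,))
        t[first:] = vals
        return t

    def scalar(name, default):
        if name not in blocks:
            return default
        return type(default)(blocks[name][0])

    ninio = blocks.get("ninio", ["50", "300"])
    model = EnergyModel(
        stack=stack,
        dangle5=dangle("dangle5"),
        dangle3=dangle("dangle3"),
        hairpin=loop("hairpin", 3),
        bulge=loop("bulge", 1),
        internal=loop("internal", 2),
        ninio_m=int(ninio[0]),
        ninio_max=int(ninio[1]),
        lxc=scalar("lxc", 107.856),
        terminal_au=scalar("terminal_au", 50),
        helix_end_blunt=scalar("helix_end_blunt", 45),
        duplex_init=scalar("duplex_init", 0),
        source=src,
    )
    logger.info("energy model %s checksum %s", src, model.checksum())
    return model


_DEFAULT_MODEL: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_energy_model()
    return _DEFAULT_MODEL


@dataclass(frozen=True)
class DuplexMatch:
    """One hybridization solution between a query and a target strand."""

    dg: float                              # kcal/mol
    pairs: tuple[tuple[int, int], ...]     # (query_index, target_index)
    query: str
    target: str

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.pairs[0][0], self.pairs[-1][0] + 1)

    @property
    def target_span(self) -> tuple[int, int]:
        return (self.pairs[-1][1], self.pairs[0][1] + 1)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def target_positions(self) -> tuple[int, ...]:
        """Paired target indices in ascending order."""
        return tuple(sorted(j for _, j in self.pairs))

    def render(self) -> str:
        """Four-line alignment text in the style of hybridization tools:
        unpaired target / paired target / paired query / unpaired query."""
        q, t = self.query, self.target
        pq = {i for i, _ in self.pairs}
        pt = {j for _, j in self.pairs}
        # walk target 5'->3' on top, query 3'->5' underneath
        pair_of_t = {j: i for i, j in self.pairs}
        top_un, top_p, bot_p, bot_un = [], [], [], []

        def emit(tu, tp, bp, bu):
            top_un.append(tu); top_p.append(tp); bot_p.append(bp); bot_un.append(bu)

        ti, qi = 0, len(q) - 1
        while ti < len(t) or qi >= 0:
            t_paired = ti < len(t) and ti in pt
            q_paired = qi >= 0 and qi in pq
            if t_paired and q_paired and pair_of_t[ti] == qi:
                emit(" ", t[ti], q[qi], " ")
                ti += 1
                qi -= 1
            elif ti < len(t) and not t_paired:
                emit(t[ti], " ", " ", " ")
                ti += 1
            elif qi >= 0 and not q_paired:
                emit(" ", " ", " ", q[qi])
                qi -= 1
            else:  # interleave remaining paired columns deterministically
                emit(t[ti], " ", " ", " ")
                ti += 1
        lines = [
            "target 5' " + "".join(top_un) + " 3'",
            "          " + "".join(top_p),
            "          " + "".join(bot_p),
            "query  3' " + "".join(bot_un) + " 5'",
        ]
        return "\n".join(lines) + f"\nmfe: {self.dg:.1f} kcal/mol"


def _pairs_valid(q_enc, t_enc, pairs) -> bool:
    last_i, last_j = -1, len(t_enc)
    for i, j in pairs:
        if not (0 <= i < len(q_enc) and 0 <= j < len(t_enc)):
            return False
        if not (i > last_i and j < last_j):
            return False
        if PT[q_enc[i], t_enc[j]] < 0:
            return False
        last_i, last_j = i, j
    return len(pairs) > 0


def _loop_cost(model: EnergyModel, q_enc, t_enc, k, l, i, j) -> int:
    """Cost of the loop between consecutive pairs (k,l) -> (i,j)."""
    a, b = i - k - 1, l - j - 1
    outer = PT[q_enc[k], t_enc[l]]
    inner = PT[t_enc[j], q_enc[i]]  # inner pair read reversed
    if a == 0 and b == 0:
        return int(model.stack[outer, inner])
    if a == 0 or b == 0:
        size = a + b
        cost = model.loop_size_penalty(model.bulge, size)
        if size == 1:  # single-nucleotide bulge: helix stacking is retained
            cost += int(model.stack[outer, inner])
        return cost
    cost = model.loop_size_penalty(model.internal, a + b)
    cost += min(model.ninio_max, model.ninio_m * abs(a - b))
    return cost


def _end_terms(model: EnergyModel, q_enc, t_enc, i, j, which: str) -> int:
    """Dangling-end / blunt-end energy at a duplex helix end.

    ``which`` is "left" for the first pair (query 5' / target 3' side) or
    "right" for the last pair (query 3' / target 5' side).
    """
    e = 0
    has = False
    if which == "left":
        ty = PT[q_enc[i], t_enc[j]]
        if i - 1 >= 0 and q_enc[i - 1] != 0:
            e += int(model.dangle5[ty, q_enc[i - 1]]); has = True
        if j + 1 < len(t_enc) and t_enc[j + 1] != 0:
            e += int(model.dangle3[ty, t_enc[j + 1]]); has = True
    else:
        ty = PT[t_enc[j], q_enc[i]]  # flipped orientation at the far end
        if j - 1 >= 0 and t_enc[j - 1] != 0:
            e += int(model.dangle5[ty, t_enc[j - 1]]); has = True
        if i + 1 < len(q_enc) and q_enc[i + 1] != 0:
            e += int(model.dangle3[ty, q_enc[i + 1]]); has = True
    return e if has else model.helix_end_blunt


def score_duplex(
    query: str, target: str, pairs: Sequence[tuple[int, int]],
    model: EnergyModel | None = None,
) -> float:
    """Free energy (kcal/mol) of a fixed intermolecular structure.

    The same scoring is used by the dynamic program and by the exhaustive
    enumerator, so a reported ``dg`` is always recomputable from
    ``DuplexMatch.pairs``.
    """
    model = model or default_model()
    q_enc, t_enc = encode(query), encode(target)
    pairs = sorted(pairs)
    if not _pairs_valid(q_enc, t_enc, pairs):
        raise ValueError("invalid pair set for these strands")
    cents = model.duplex_init
    for (k, l), (i, j) in zip(pairs, pairs[1:]):
        cents += _loop_cost(model, q_enc, t_enc, k, l, i, j)
    cents += _end_terms(model, q_enc, t_enc, *pairs[0], "left")
    cents += _end_terms(model, q_enc, t_enc, *pairs[-1], "right")
    return cents / 100.0


def duplex_mfe(
    query: str,
    target: str,
    model: EnergyModel | None = None,
    limits: LoopLimits | None = None,
) -> DuplexMatch | None:
    """Minimum-free-energy intermolecular hybridization, or None (no-match)
    when no allowed pair exists between the strands.

    Ties are broken deterministically: lower energy, then more pairs, then
    leftmost query span, then lexicographically smallest pair list.
    """
    model = model or default_model()
    limits = limits or LoopLimits()
    q_enc, t_enc = encode(query), encode(target)
    n, m = len(q_enc), len(t_enc)
    if n == 0 or m == 0:
        raise ValueError("sequences must be non-empty")

    # cell value: (cents, -n_pairs, q_start, pairs_tuple) — lexicographic min
    V: list[list[tuple | None]] = [[None] * m for _ in range(n)]
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if PT[q_enc[i], t_enc[j]] < 0:
                continue
            best = (
                _end_terms(model, q_enc, t_enc, i, j, "left"),
                -1, i, ((i, j),),
            )
            for k in range(i):
                for l in range(m - 1, j, -1):
                    prev = V[k][l]
                    if prev is None:
                        continue
                    a, b = i - k - 1, l - j - 1
                    if a and b:
                        if a > limits.max_internal or b > limits.max_internal:
                            continue
                    elif a + b > limits.max_bulge:
                        continue
                    cost = _loop_cost(model, q_enc, t_enc, k, l, i, j)
                    cand = (
                        prev[0] + cost, prev[1] - 1, prev[2],
                        prev[3] + ((i, j),),
                    )
                    if cand < best:
                        best = cand
            V[i][j] = best

    total_best = None
    for i in range(n):
        for j in range(m):
            if V[i][j] is None:
                continue
            cents, negp, qs, prs = V[i][j]
            cents += _end_terms(model, q_enc, t_enc, i, j, "right")
            cand = (cents, negp, qs, prs)
            if total_best is None or cand < total_best:
                total_best = cand
    if total_best is None:
        return None
    cents, _negp, _qs, prs = total_best
    cents += model.duplex_init
    return DuplexMatch(dg=cents / 100.0, pairs=prs, query=query, target=target)


def duplex_mfe_batch(
    queries: np.ndarray,
    target: str,
    model: EnergyModel | None = None,
    limits: LoopLimits | None = None,
) -> np.ndarray:
    """MFE in centi-kcal for a batch of equal-length queries vs one target.

    ``queries`` is a (B, n) uint8 array of encoded windows.  Returns a
    (B,) int64 array; entries with no possible pairing hold ``INF``.
    Vectorized over the batch; used by the genome scanner.
    """
    model = model or default_model()
    limits = limits or LoopLimits()
    t_enc = encode(target)
    B, n = queries.shape
    m = len(t_enc)
    pt = PT[queries[:, :, None], t_enc[None, None, :]].astype(np.int64)   # (B,n,m)
    ptr = PT[t_enc[None, None, :], queries[:, :, None]].astype(np.int64)  # reversed
    valid = pt >= 0
    pt_safe = np.where(valid, pt, 0)
    ptr_safe = np.where(valid, ptr, 0)

    # left-end terms per cell
    left = np.zeros((B, n, m), dtype=np.int64)
    d5 = model.dangle5.astype(np.int64)
    d3 = model.dangle3.astype(np.int64)
    for i in range(n):
        for j in range(m):
            contrib = np.zeros(B, dtype=np.int64)
            h = np.zeros(B, dtype=bool)
            if i - 1 >= 0:
                base = queries[:, i - 1].astype(np.int64)
                ok = base != 0
                contrib += np.where(ok, d5[pt_safe[:, i, j], base], 0)
                h |= ok
            if j + 1 < m and t_enc[j + 1] != 0:
                contrib += d3[pt_safe[:, i, j], int(t_enc[j + 1])]
                h |= True
            left[:, i, j] = np.where(h, contrib, model.helix_end_blunt)

    stack = model.stack.astype(np.int64)
    bulge_pen = model.bulge.astype(np.int64)
    internal_pen = model.internal.astype(np.int64)

    V = np.full((B, n, m), INF, dtype=np.int64)
    for i in range(n):
        for j in range(m):
            best = left[:, i, j].copy()
            inner = ptr_safe[:, i, j]
            for k in range(i):
                a = i - k - 1
                for l in range(m - 1, j, -1):
                    b = l - j - 1
                    if a and b:
                        if a > limits.max_internal or b > limits.max_internal:
                            continue
                        cost = int(internal_pen[min(a + b, 30)]) + min(
                            model.ninio_max, model.ninio_m * abs(a - b)
                        )
                        cand = V[:, k, l] + cost
                    elif a + b == 0:
                        cand = V[:, k, l] + stack[pt_safe[:, k, l], inner]
                    else:
                        s = a + b
                        if s > limits.max_bulge:
                            continue
                        cost = int(bulge_pen[min(s, 30)])
                        cand = V[:, k, l] + cost
                        if s == 1:
                            cand = cand + stack[pt_safe[:, k, l], inner]
                    np.minimum(best, cand, out=best)
            V[:, i, j] = np.where(valid[:, i, j], best, INF)

    # right-end terms and global minimum
    total = np.full(B, INF, dtype=np.int64)
    for i in range(n):
        for j in range(m):
            contrib = np.zeros(B, dtype=np.int64)
            h = np.zeros(B, dtype=bool)
            fty = ptr_safe[:, i, j]
            if j - 1 >= 0 and t_enc[j - 1] != 0:
                contrib += d5[fty, int(t_enc[j - 1])]
                h |= True
            if i + 1 < n:
                base = queries[:, i + 1].astype(np.int64)
                ok = base != 0
                contrib += np.where(ok, d3[fty, base], 0)
                h |= ok
            right = np.where(h, contrib, model.helix_end_blunt)
            cand = np.where(valid[:, i, j], V[:, i, j] + right, INF)
            np.minimum(total, cand, out=total)
    total = np.where(total < INF, total + model.duplex_init, total)
    return total


def enumerate_duplex_structures(
    query: str,
    target: str,
    model: EnergyModel | None = None,
    limits: LoopLimits | None = None,
) -> DuplexMatch | None:
    """Exhaustive-enumeration oracle: scores every monotonic, pseudoknot-
    free set of allowed pairs and returns the optimum (test use only).

    Guarded to len(query) * len(target) <= 100.
    """
    model = model or default_model()
    limits = limits or LoopLimits()
    if len(query) * len(target) > 100:
        raise ValueError("enumeration guard: len(query)*len(target) > 100")
    q_enc, t_enc = encode(query), encode(target)
    n, m = len(q_enc), len(t_enc)
    allowed = [
        (i, j) for i in range(n) for j in range(m) if PT[q_enc[i], t_enc[j]] >= 0
    ]
    best: tuple | None = None

    def admissible(cur, i, j):
        if not cur:
            return True
        k, l = cur[-1]
        if not (i > k and j < l):
            return False
        a, b = i - k - 1, l - j - 1
        if a and b:
            return a <= limits.max_internal and b <= limits.max_internal
        return a + b <= limits.max_bulge

    def rec(cur: list, start: int):
        nonlocal best
        if cur:
            cents = round(score_duplex(query, target, cur, model) * 100)
            cand = (cents, -len(cur), cur[0][0], tuple(cur))
            if best is None or cand < best:
                best = cand
        for idx in range(start, len(allowed)):
            i, j = allowed[idx]
            if admissible(cur, i, j):
                cur.append((i, j))
                rec(cur, idx + 1)
                cur.pop()

    # allowed is sorted by (i, j); recursion explores subsets in index order,
    # the admissibility check enforces monotonicity
    order = sorted(allowed)
    allowed = order
    rec([], 0)
    if best is None:
        return None
    cents, _np_, _qs, prs = best
    return DuplexMatch(dg=cents / 100.0, pairs=prs, query=query, target=target)


def derive_sd_threshold(
    model: EnergyModel | None = None,
    reference_tail: str = CANONICAL_TAIL,
) -> float:
    """SD-calling threshold: the mean hybridization energy of the four SD
    tetramers against the canonical anti-SD tail, rounded to one decimal.

    With the shipped tables the four energies are -7.1, -8.0, -9.3 and
    -9.1 kcal/mol and the threshold is -8.4 kcal/mol.
    """
    model = model or default_model()
    energies = []
    for tet in SD_TETRAMERS:
        match = duplex_mfe(tet, reference_tail, model)
        energies.append(0.0 if match is None else match.dg)
    return round(sum(energies) / len(energies), 1)
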