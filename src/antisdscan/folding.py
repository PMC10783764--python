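"""Minimum-free-energy intramolecular folding of short RNAs.

A Zuker-style dynamic program restricted to hairpins, stacks, bulges and
internal loops — no multi-branch loops, which short 3'-terminal regions
do not need.  The model reuses the duplex nearest-neighbor tables plus the
hairpin-loop length penalties; helix ends (the hairpin-closing pair, both
closing pairs of a bulge/internal loop, and external-facing pairs) pay the
terminal AU/GU penalty.  No dangling-end terms are applied.

Used to delimit the unstructured 3' tail of 16S rRNA: the tail is
everything strictly 3' of the last paired base of the MFE structure.
"""

from __future__ import annotations

from typing import Sequence

from .thermo import INF, PT, EnergyModel, default_model, encode

MIN_HAIRPIN_LOOP = 3
MAX_LOOP_SPAN = 30  # total unpaired bases allowed in one bulge/internal loop


def _termau(model: EnergyModel, ty: int) -> int:
    # pair order CG GC GU UG AU UA: indices >= 2 are GU/AU-type ends
    return model.terminal_au if ty >= 2 else 0


def _transition(model: EnergyModel, enc, i, j, k, l) -> int | None:
    """Energy of the loop closed by (i,j) with inner pair (k,l)."""
    a, b = k - i - 1, j - l - 1
    outer = PT[enc[i], enc[j]]
    inner = PT[enc[l], enc[k]]  # reversed orientation for table lookup
    if a == 0 and b == 0:
        return int(model.stack[outer, inner])
    if a == 0 or b == 0:
        size = a + b
        if size > MAX_LOOP_SPAN:
            return None
        cost = model.loop_size_penalty(model.bulge, size)
        if size == 1:
            return cost + int(model.stack[outer, inner])
        return cost + _termau(model, outer) + _termau(model, inner)
    if a + b > MAX_LOOP_SPAN:
        return None
    cost = model.loop_size_penalty(model.internal, a + b)
    cost += min(model.ninio_max, model.ninio_m * abs(a - b))
    return cost + _termau(model, outer) + _termau(model, inner)


def score_structure(
    seq: str, pairs: Sequence[tuple[int, int]], model: EnergyModel | None = None
) -> float:
    """Free energy (kcal/mol) of a fixed nested structure.

    Raises ValueError for pseudoknots, multi-branch loops, or loops larger
    than the model allows.  Shared currency between the dynamic program
    and the exhaustive test oracle.
    """
    model = model or default_model()
    enc = encode(seq)
    pairs = sorted(pairs)
    partner = {}
    for i, j in pairs:
        if i >= j or PT[enc[i], enc[j]] < 0:
            raise ValueError(f"invalid pair {(i, j)}")
        partner[i] = j
        partner[j] = i
    # check nesting
    stack_ = []
    for x in range(len(seq)):
        if x in partner and partner[x] > x:
            stack_.append(x)
        elif x in partner:
            if not stack_ or partner[x] != stack_.pop():
                raise ValueError("pseudoknotted structure")
    cents = 0
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    roots = []
    open_ = []
    for i, j in pairs:  # sorted by i; find enclosing pair
        while open_ and open_[-1][1] < i:
            open_.pop()
        if open_:
            children[open_[-1]].append((i, j))
        else:
            roots.append((i, j))
        open_.append((i, j))
    for (i, j), kids in children.items():
        ty = PT[enc[i], enc[j]]
        if not kids:
            loop = j - i - 1
            if loop < MIN_HAIRPIN_LOOP:
                raise ValueError(f"hairpin loop < {MIN_HAIRPIN_LOOP}")
            cents += model.loop_size_penalty(model.hairpin, loop)
            cents += _termau(model, ty)
        elif len(kids) == 1:
            t = _transition(model, enc, i, j, *kids[0])
            if t is None:
                raise ValueError("loop larger than model allows")
            cents += t
        else:
            raise ValueError("multi-branch loop not in model")
    for i, j in roots:
        cents += _termau(model, PT[enc[i], enc[j]])
    return cents / 100.0


def fold_mfe(
    seq: str, model: EnergyModel | None = None
) -> tuple[float, list[tuple[int, int]]]:
    """MFE structure of a short RNA; returns (energy kcal/mol, pairs).

    An empty pair list (energy 0.0) means the sequence is unstructured.
    """
    model = model or default_model()
    if not seq:
        raise ValueError("empty sequence")
    enc = encode(seq)
    n = len(enc)
    V = [[INF] * n for _ in range(n)]
    VB = [[None] * n for _ in range(n)]  # back-pointer: inner pair or None
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            ty = PT[enc[i], enc[j]]
            if ty < 0:
                continue
            best = model.loop_size_penalty(model.hairpin, j - i - 1) + _termau(
                model, ty
            )
            back = None
            for k in range(i + 1, j):
                for l in range(j - 1, k, -1):
                    if V[k][l] >= INF:
                        continue
                    t = _transition(model, enc, i, j, k, l)
                    if t is None:
                        continue
                    cand = V[k][l] + t
                    if cand < best:
                        best, back = cand, (k, l)
            V[i][j] = best
            VB[i][j] = back
    # external: W[x] = best energy of prefix seq[:x]
    W = [0] * (n + 1)
    WB: list[tuple[int, int] | None] = [None] * (n + 1)
    for x in range(1, n + 1):
        best, back = W[x - 1], None
        j = x - 1
        for i in range(j):
            if V[i][j] >= INF:
                continue
            cand = W[i] + V[i][j] + _termau(model, PT[enc[i], enc[j]])
            if cand < best:
                best, back = cand, (i, j)
        W[x] = best
        WB[x] = back
    pairs: list[tuple[int, int]] = []

    def trace_v(i, j):
        pairs.append((i, j))
        back = VB[i][j]
        if back is not None:
            trace_v(*back)

    x = n
    while x > 0:
        back = WB[x]
        if back is None:
            x -= 1
        else:
            i, j = back
            trace_v(i, j)
            x = i
    return W[n] / 100.0, sorted(pairs)


def enumerate_structures(
    seq: str, model: EnergyModel | None = None
) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Exhaustive oracle: minimum over every pseudoknot-free, multiloop-free
    structure, scored with :func:`score_structure`.  Inputs <= 20 nt."""
    model = model or default_model()
    if len(seq) > 20:
        raise ValueError("enumeration guard: sequence longer than 20 nt")
    enc = encode(seq)
    n = len(enc)

    def closed(i, j):
        """Yield pair chains for a structure closed by (i, j)."""
        yield ((i, j),)
        for k in range(i + 1, j):
            for l in range(k + MIN_HAIRPIN_LOOP + 1, j):
                if PT[enc[k], enc[l]] >= 0:
                    for chain in closed(k, l):
                        yield ((i, j),) + chain

    def external(start):
        yield ()
        for i in range(start, n):
            for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
                if PT[enc[i], enc[j]] >= 0:
                    for chain in closed(i, j):
                        for rest in external(j + 1):
                            yield chain + rest

    best_e, best_s = 0.0, ()
    for structure in external(0):
        if not structure:
            continue
        try:
            e = score_structure(seq, structure, model)
        except ValueError:
            continue
        if e < best_e or (e == best_e and structure < best_s):
            best_e, best_s = e, structure
    return best_e, best_s
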