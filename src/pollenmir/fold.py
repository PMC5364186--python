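"""RNA secondary-structure prediction for hairpin screening.

The built-in engine is a deliberately simple stacking-score model, not a
thermodynamic nearest-neighbour model: it finds the nested structure
minimising

    E = -2 * (number of stacked pair steps) + 1 * (non-hairpin closings)

subject to helices of at least 3 consecutive pairs, hairpin loops of at
least 3 nt, and Watson-Crick plus G:U pairing.  Every helix is "closed"
either by a hairpin loop (cost 0) or by a loop containing further
structure (bulge, interior or multibranch loop; cost +1).  A single
perfect stem of P pairs therefore scores -2(P-1).

An external thermodynamic engine (ViennaRNA, ``engine="vienna"``) can be
plugged in behind the same (structure, mfe) contract; free-energy
thresholds quoted in kcal/mol are calibrated to such engines.
"""

from __future__ import annotations

from typing import Callable, List, Tuple, Union

import numpy as np

MIN_HELIX = 3
MIN_LOOP = 3
_STACK_BONUS = -2
_OPEN_PENALTY = 1
_INF = 1 << 20

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
# allowed pairs: AU, UA, CG, GC, GU, UG
_CANPAIR = np.zeros((4, 4), dtype=np.uint8)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _CANPAIR[_a, _b] = 1


def _fill_tables(enc, canpair):  # njit-compiled below when numba is present
    n = enc.shape[0]
    V = np.full((n, n), _INF, dtype=np.int32)
    W = np.full((n, n), _INF, dtype=np.int32)  # min energy with >=1 helix
    for span in range(2 * MIN_HELIX - 1, n):  # j - i
        for i in range(0, n - span):
            j = i + span
            # --- V: helix with outer pair exactly (i, j) ---
            best_v = _INF
            h = 0
            while True:
                ii = i + h
                jj = j - h
                if ii >= jj or canpair[enc[ii], enc[jj]] == 0:
                    break
                h += 1
                if h < MIN_HELIX:
                    continue
                stack_e = _STACK_BONUS * (h - 1)
                # hairpin closing
                if j - i - 2 * h + 1 >= MIN_LOOP:
                    if stack_e < best_v:
                        best_v = stack_e
                # closing onto inner structure
                if i + h < j - h and W[i + h, j - h] < _INF:
                    cand = stack_e + _OPEN_PENALTY + W[i + h, j - h]
                    if cand < best_v:
                        best_v = cand
            V[i, j] = best_v
            # --- W: at least one helix somewhere in [i, j] ---
            best_w = best_v
            if W[i + 1, j] < best_w:
                best_w = W[i + 1, j]
            if W[i, j - 1] < best_w:
                best_w = W[i, j - 1]
            for k in range(i + 1, j):
                if W[i, k] < _INF and W[k + 1, j] < _INF:
                    cand = W[i, k] + W[k + 1, j]
                    if cand < best_w:
                        best_w = cand
            W[i, j] = best_w
    return V, W


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _fill_tables_fast = njit(cache=True)(_fill_tables)
except ImportError:  # pragma: no cover
    _fill_tables_fast = _fill_tables


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in sequence.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-ACGTU character in sequence: {exc}") from None


def _traceback(enc, canpair, V, W) -> List[Tuple[int, int]]:
    pairs: List[Tuple[int, int]] = []
    n = enc.shape[0]
    if n == 0 or W[0, n - 1] >= 0:
        return pairs
    stack = [("W", 0, n - 1)]
    while stack:
        state, i, j = stack.pop()
        if j - i < 2 * MIN_HELIX - 1:
            continue
        if state == "W":
            e = W[i, j]
            if e >= _INF or e >= 0 and (i, j) != (0, n - 1):
                continue
            if V[i, j] == e:
                stack.append(("V", i, j))
            elif W[i + 1, j] == e:
                stack.append(("W", i + 1, j))
            elif W[i, j - 1] == e:
                stack.append(("W", i, j - 1))
            else:
                for k in range(i + 1, j):
                    if W[i, k] < _INF and W[k + 1, j] < _INF and W[i, k] + W[k + 1, j] == e:
                        stack.append(("W", i, k))
                        stack.append(("W", k + 1, j))
                        break
        else:  # V
            e = V[i, j]
            h = 0
            found = False
            while not found:
                ii, jj = i + h, j - h
                if ii >= jj or canpair[enc[ii], enc[jj]] == 0:
                    break
                h += 1
                if h < MIN_HELIX:
                    continue
                stack_e = _STACK_BONUS * (h - 1)
                if j - i - 2 * h + 1 >= MIN_LOOP and stack_e == e:
                    for t in range(h):
                        pairs.append((i + t, j - t))
                    found = True
                elif (
                    i + h < j - h
                    and W[i + h, j - h] < _INF
                    and stack_e + _OPEN_PENALTY + W[i + h, j - h] == e
                ):
                    for t in range(h):
                        pairs.append((i + t, j - t))
                    stack.append(("W", i + h, j - h))
                    found = True
    return pairs


def fold_builtin(sequence: str) -> Tuple[str, float]:
    """Minimum-score structure under the built-in stacking model."""
    enc = _encode(sequence)
    n = len(enc)
    if n < 2 * MIN_HELIX + MIN_LOOP:
        return "." * n, 0.0
    V, W = _fill_tables_fast(enc, _CANPAIR)
    mfe = int(W[0, n - 1])
    if mfe >= 0:
        return "." * n, 0.0
    pairs = _traceback(enc, _CANPAIR, V, W)
    dots = ["."] * n
    for a, b in pairs:
        dots[a] = "("
        dots[b] = ")"
    return "".join(dots), float(mfe)


def fold_vienna(sequence: str) -> Tuple[str, float]:
    """Thermodynamic MFE folding via the ViennaRNA bindings."""
    _encode(sequence)  # alphabet check with the same error contract
    import RNA

    structure, mfe = RNA.fold(sequence.upper().replace("T", "U"))
    return structure, float(mfe)


Engine = Union[str, Callable[[str], Tuple[str, float]]]


def fold(sequence: str, engine: Engine = "builtin") -> Tuple[str, float]:
    """Fold a sequence with the selected engine.

    Returns a balanced dot-bracket string of the same length and the
    structure score/energy (<= 0; 0 with an all-dot structure when nothing
    pairs).
    """
    if callable(engine):
        return engine(sequence)
    if engine == "builtin":
        return fold_builtin(sequence)
    if engine == "vienna":
        return fold_vienna(sequence)
    raise ValueError(f"unknown folding engine {engine!r}")


def pair_table(structure: str) -> np.ndarray:
    """Partner index per position (-1 when unpaired); errors if unbalanced."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    stack: List[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            a = stack.pop()
            pt[a] = i
            pt[i] = a
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pt
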