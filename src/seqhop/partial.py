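"""Partial-SMILES feasibility.

`is_extensible(prefix)` decides whether some suffix could turn the prefix
into a valid SMILES.  It is used by the decoder's invalid-filtering option
to discard doomed hypotheses after every emitted token, so it must be cheap
and — crucially — conservative: it may accept a prefix that no suffix can
actually rescue (the final molecule is still re-checked with the full
parser), but it must never reject a prefix of a valid SMILES.

Checks performed:

* grammar transitions (what may follow an atom, a bond, a branch symbol,
  a ring-closure digit, a dot);
* branch feasibility — a ``)`` must have a matching ``(``;
* ring-bond feasibility — a ring closure must not bond an atom to itself
  nor duplicate an existing bond;
* valence feasibility — the bond orders already committed to an atom
  (including opened-but-unclosed ring bonds) must not exceed a permissive
  maximum valence for its element.

Aromaticity, kekulisation and chirality are deliberately not modelled:
they could only turn "extensible" into "not extensible", and erring on the
permissive side keeps the invariant `is_valid(s) => is_extensible(p)` for
every prefix p of s.
"""

from __future__ import annotations

import re

__all__ = ["is_extensible"]

# Permissive maximum valence by element symbol (upper bound over the
# element's allowed SMILES valence states).  Unknown elements get 8.
_MAX_VALENCE = {
    "B": 3, "C": 4, "N": 5, "O": 2, "P": 5, "S": 6,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
    "b": 3, "c": 4, "n": 4, "o": 2, "p": 5, "s": 4,
    "*": 8,
}

_BOND_ORDER = {"-": 1, "=": 2, "#": 3, "$": 4, ":": 1, "/": 1, "\\": 1}

_BRACKET_RE = re.compile(
    r"\[(?P<isotope>\d+)?(?P<symbol>[A-Za-z][a-z]?|\*)(?P<chiral>@{1,2}(?:TH|AL|SP|TB|OH)?\d*)?"
    r"(?P<hcount>H\d*)?(?P<charge>[+-]+\d*|\+\d+|-\d+)?(?::\d+)?\]$"
)

# grammar states
_START, _ATOM, _BOND, _OPEN, _CLOSE, _DOT = range(6)


class _Atom:
    __slots__ = ("symbol", "used", "max_valence")

    def __init__(self, symbol: str, max_valence: int):
        self.symbol = symbol
        self.used = 0
        self.max_valence = max_valence


def _bracket_max_valence(token: str) -> int | None:
    """Remaining bondable valence of a bracket atom, or None if malformed."""
    m = _BRACKET_RE.match(token)
    if not m:
        return None
    sym = m.group("symbol")
    base = _MAX_VALENCE.get(sym, _MAX_VALENCE.get(sym.capitalize(), 8))
    charge = 0
    ch = m.group("charge")
    if ch:
        if ch in ("+", "-"):
            charge = 1 if ch == "+" else -1
        elif set(ch) <= {"+"}:
            charge = len(ch)
        elif set(ch) <= {"-"}:
            charge = -len(ch)
        else:
            charge = int(ch)
    hc = m.group("hcount")
    hydrogens = 0
    if hc:
        hydrogens = 1 if hc == "H" else int(hc[1:])
    # a positive charge can open an extra bonding site, a negative one
    # removes one; explicit hydrogens consume sites
    return max(0, base + charge - hydrogens) if sym != "*" else 8


def is_extensible(prefix: str) -> bool:  # noqa: C901 - single cohesive scanner
    """True iff some suffix could complete ``prefix`` into a valid SMILES."""
    if prefix == "":
        return True  # any valid SMILES extends the empty prefix

    atoms: list[_Atom] = []
    bonds: set[tuple[int, int]] = set()
    # ring number -> (atom index, bond order or None)
    open_rings: dict[int, tuple[int, int | None]] = {}
    branch_stack: list[int] = []  # attachment atom at each open '('
    attach: int | None = None  # atom new bonds hang off
    state = _START
    pending_bond: int | None = None  # explicit bond order awaiting its atom

    def add_atom(symbol: str, max_val: int) -> bool:
        nonlocal attach, pending_bond, state
        atoms.append(_Atom(symbol, max_val))
        idx = len(atoms) - 1
        if attach is not None and state != _DOT:
            order = pending_bond if pending_bond is not None else 1
            atoms[attach].used += order
            atoms[idx].used += order
            if atoms[attach].used > atoms[attach].max_valence:
                return False
            if atoms[idx].used > atoms[idx].max_valence:
                return False
            bonds.add((min(attach, idx), max(attach, idx)))
        pending_bond = None
        attach = idx
        state = _ATOM
        return True

    def close_ring(num: int) -> bool:
        nonlocal state
        if attach is None:
            return False
        if num in open_rings:
            other, order0 = open_rings.pop(num)
            if other == attach:
                return False  # ring bond to self
            pair = (min(other, attach), max(other, attach))
            if pair in bonds:
                return False  # duplicate bond
            order = pending_bond if pending_bond is not None else (order0 or 1)
            # the opening atom already reserved one unit on opening; charge
            # the difference, and the full order on the closing atom
            atoms[other].used += order - (order0 or 1)
            atoms[attach].used += order
            if atoms[other].used > atoms[other].max_valence:
                return False
            if atoms[attach].used > atoms[attach].max_valence:
                return False
            bonds.add(pair)
        else:
            order = pending_bond
            open_rings[num] = (attach, order)
            # reserve one bonding unit for the eventual closure
            atoms[attach].used += order or 1
            if atoms[attach].used > atoms[attach].max_valence:
                return False
        state = _ATOM
        return True

    i, n = 0, len(prefix)
    while i < n:
        ch = prefix[i]
        if ch == "[":
            j = prefix.find("]", i)
            if j < 0:
                # incomplete bracket atom at end of prefix: fine if it is a
                # plausible bracket-body prefix (no nested '[')
                body = prefix[i + 1 :]
                return "[" not in body and "]" not in body
            token = prefix[i : j + 1]
            max_val = _bracket_max_valence(token)
            if max_val is None:
                return False
            if not add_atom(token, max_val if max_val > 0 else 0):
                return False
            i = j + 1
        elif ch in ("C", "B") and prefix[i : i + 2] in ("Cl", "Br"):
            if not add_atom(prefix[i : i + 2], _MAX_VALENCE[prefix[i : i + 2]]):
                return False
            i += 2
        elif ch in "BCNOPSFIbcnops*":
            if not add_atom(ch, _MAX_VALENCE[ch]):
                return False
            i += 1
        elif ch in _BOND_ORDER:
            # a bond may open a branch body ("C(=O)...") as well as follow
            # an atom or a closed branch
            if state not in (_ATOM, _CLOSE, _OPEN) or pending_bond is not None:
                return False
            pending_bond = _BOND_ORDER[ch]
            state = _BOND
            i += 1
        elif ch.isdigit() or ch == "%":
            # ring-closure digits may follow an atom, a bond symbol, or a
            # closed branch ("C(C)1CCCC1" is accepted by the full parser)
            if state not in (_ATOM, _BOND, _CLOSE):
                return False
            if ch == "%":
                digits = prefix[i + 1 : i + 3]
                if len(digits) < 2:
                    return digits.isdigit() or digits == ""  # trailing partial %n
                if not digits.isdigit():
                    return False
                num = int(digits)
                i += 3
            else:
                num = int(ch)
                i += 1
            if not close_ring(num):
                return False
            pending_bond = None
        elif ch == "(":
            if state not in (_ATOM, _CLOSE) or attach is None:
                return False
            branch_stack.append(attach)
            state = _OPEN
            i += 1
        elif ch == ")":
            if not branch_stack:
                return False
            if state in (_BOND, _OPEN, _DOT):
                return False  # dangling bond / empty branch cannot be fixed
            attach = branch_stack.pop()
            state = _CLOSE
            i += 1
        elif ch == ".":
            if state not in (_ATOM, _CLOSE) or branch_stack:
                return False
            if pending_bond is not None:
                return False
            attach = None
            state = _DOT
            i += 1
        else:
            return False  # character outside the SMILES lexicon
    return True
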