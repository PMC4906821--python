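"""Henderson-Hasselbalch fractional charges for ionizable groups."""

from __future__ import annotations

from .constants import ACIDIC_GROUPS, BASIC_GROUPS, PKA_TABLE


def titrate_charge(group: str, ph: float, pka_table: dict[str, float] | None = None) -> float:
    """Mean charge (in units of e) of an ionizable group at a given pH.

    Acids (Asp, Glu, Cys, Tyr, C-terminus) titrate between 0 and -1:
    ``q = -1 / (1 + 10**(pKa - pH))``.  Bases (His, Lys, Arg, N-terminus)
    titrate between +1 and 0: ``q = +1 / (1 + 10**(pH - pKa))``.

    Parameters
    ----------
    group
        3-letter residue code or terminal tag (``NTERM`` / ``CTERM``).
    ph
        Solution pH.
    pka_table
        Optional override of the model-compound pKa table.

    Returns
    -------
    float
        Signed fractional charge in ``[-1, 1]``.
    """
    table = PKA_TABLE if pka_table is None else pka_table
    key = group.upper()
    if key not in table:
        raise KeyError(f"no pKa entry for group {group!r}")
    pka = table[key]
    if key in ACIDIC_GROUPS:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))
    if key in BASIC_GROUPS:
        return +1.0 / (1.0 + 10.0 ** (ph - pka))
    raise KeyError(f"group {group!r} is neither acidic nor basic")


def formal_charge(group: str) -> float:
    """Integer charge of the predominant species at neutral pH: acids -1, bases +1."""
    key = group.upper()
    if key in ACIDIC_GROUPS:
        return -1.0
    if key in BASIC_GROUPS:
        return +1.0
    raise KeyError(f"group {group!r} is not ionizable")
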