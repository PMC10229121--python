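"""Independent brute-force oracles used by the tests.

The mass oracle sums atomic monoisotopic masses over per-residue elemental
formulas -- a different route from the package's residue-mass table, so the
two can cross-check each other.
"""

import math

# AME2020/IUPAC monoisotopic atomic masses (Da)
_ATOM = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

# residue (= amino acid - water) elemental compositions
_FORMULA = {
    "G": dict(C=2, H=3, N=1, O=1),
    "A": dict(C=3, H=5, N=1, O=1),
    "S": dict(C=3, H=5, N=1, O=2),
    "P": dict(C=5, H=7, N=1, O=1),
    "V": dict(C=5, H=9, N=1, O=1),
    "T": dict(C=4, H=7, N=1, O=2),
    "C": dict(C=3, H=5, N=1, O=1, S=1),
    "L": dict(C=6, H=11, N=1, O=1),
    "I": dict(C=6, H=11, N=1, O=1),
    "N": dict(C=4, H=6, N=2, O=2),
    "D": dict(C=4, H=5, N=1, O=3),
    "Q": dict(C=5, H=8, N=2, O=2),
    "K": dict(C=6, H=12, N=2, O=1),
    "E": dict(C=5, H=7, N=1, O=3),
    "M": dict(C=5, H=9, N=1, O=1, S=1),
    "H": dict(C=6, H=7, N=3, O=1),
    "F": dict(C=9, H=9, N=1, O=1),
    "R": dict(C=6, H=12, N=4, O=1),
    "Y": dict(C=9, H=9, N=1, O=2),
    "W": dict(C=11, H=10, N=2, O=1),
}

_PTM_FORMULA = {
    "me1": dict(C=1, H=2),
    "me2": dict(C=2, H=4),
    "me3": dict(C=3, H=6),
    "ac": dict(C=2, H=2, O=1),
}

ORACLE_WATER = 2 * _ATOM["H"] + _ATOM["O"]
ORACLE_PROTON = 1.00727646688
ORACLE_NH3 = _ATOM["N"] + 3 * _ATOM["H"]


def _formula_mass(formula: dict) -> float:
    return sum(_ATOM[el] * n for el, n in formula.items())


def oracle_peptide_mass(sequence: str, ptms=()) -> float:
    """Neutral monoisotopic peptide mass from atomic composition."""
    m = sum(_formula_mass(_FORMULA[ch]) for ch in sequence) + ORACLE_WATER
    m += sum(_formula_mass(_PTM_FORMULA[kind]) for _, kind in ptms)
    return m


def oracle_c_ion_mz(sequence: str, index: int, charge: int, ptms=()) -> float:
    """c-ion m/z: N-terminal residues + NH3, protonated."""
    m = sum(_formula_mass(_FORMULA[ch]) for ch in sequence[:index]) + ORACLE_NH3
    m += sum(
        _formula_mass(_PTM_FORMULA[kind]) for pos, kind in ptms if pos <= index
    )
    return (m + charge * ORACLE_PROTON) / charge


def oracle_pooled_t(a, b):
    """Textbook pooled-variance two-sample two-tailed t-test: (t, df, p)."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def oracle_sem(values) -> float:
    """Closed-form sample SEM: sqrt(sum((x-mean)^2)/(n-1))/sqrt(n)."""
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in values) / (n - 1))
    return sd / math.sqrt(n)
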