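"""Nearest-neighbor DNA duplex thermodynamics.

Unified nearest-neighbor parameters (SantaLucia 1998 style): per-stack
enthalpy (kcal/mol) and entropy (cal/mol/K) plus terminal-basepair
initiation terms.  Melting temperature uses the two-state model

    Tm = 1000 * dH / (dS + R * ln(Ct / x)) - 273.15

with R = 1.987 cal/mol/K, Ct the total strand concentration, x = 4 for a
non-self-complementary duplex (x = 1 self-complementary), and the entropic
salt correction dS += 0.368 * (N - 1) * ln[Na+].

Free energy at 37 °C is dG37 = dH - 310.15 * dS / 1000 (kcal/mol) on the
salt-corrected entropy.
"""

from __future__ import annotations

import math

from .errors import ContractError

R_GAS = 1.987  # cal / (mol K)
T37 = 310.15   # K

# stack: (dH kcal/mol, dS cal/mol/K); keys are 5'->3' top-strand dinucleotides
NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

# terminal base-pair initiation terms
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)
SYMMETRY_DS = -1.4  # self-complementary duplex entropy penalty

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_NA_MOLAR = 0.05
DEFAULT_STRAND_CONC_MOLAR = 0.25e-6


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_canonical(seq: str) -> bool:
    return bool(seq) and set(seq) <= set("ACGT")


def _check(seq: str, min_len: int = 8) -> None:
    if len(seq) < min_len:
        raise ContractError(f"sequence too short for duplex model "
                            f"({len(seq)} < {min_len} nt)")
    if not is_canonical(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise ContractError(f"non-canonical bases {bad} in sequence")


def duplex_dh_ds(seq: str) -> tuple[float, float]:
    """Raw nearest-neighbor dH (kcal/mol) and dS (cal/mol/K), no salt term."""
    _check(seq, min_len=2)
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        h, s = NN_UNIFIED[seq[i:i + 2]]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        h, s = INIT_GC if end in "GC" else INIT_AT
        dh += h
        ds += s
    if seq == reverse_complement(seq):
        ds += SYMMETRY_DS
    return dh, ds


def _salt_ds(seq: str, ds: float, na_molar: float) -> float:
    return ds + 0.368 * (len(seq) - 1) * math.log(na_molar)


def melting_temperature(seq: str, na_molar: float = DEFAULT_NA_MOLAR,
                        strand_conc_molar: float = DEFAULT_STRAND_CONC_MOLAR
                        ) -> float:
    """Two-state nearest-neighbor Tm (°C) of seq against its perfect complement."""
    _check(seq)
    dh, ds = duplex_dh_ds(seq)
    ds = _salt_ds(seq, ds, na_molar)
    x = 1.0 if seq == reverse_complement(seq) else 4.0
    return dh * 1000.0 / (ds + R_GAS * math.log(strand_conc_molar / x)) - 273.15


def delta_g37(seq: str, na_molar: float = DEFAULT_NA_MOLAR) -> float:
    """Duplex formation free energy at 37 °C (kcal/mol), salt-corrected."""
    _check(seq)
    dh, ds = duplex_dh_ds(seq)
    ds = _salt_ds(seq, ds, na_molar)
    return dh - T37 * ds / 1000.0
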