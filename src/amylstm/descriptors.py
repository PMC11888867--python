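"""Fixed-length sequence descriptors for the classical baselines.

Five feature sets are provided, following the iFeature conventions used
throughout the sequence-based protein-classification literature:

- AAC: 20 relative residue frequencies.
- DDE: 400 dipeptide deviations from the codon-usage-expected mean,
  standardized by the theoretical variance.
- CTDC: composition of 3 physicochemical groups for each of 13 attributes
  (39 features).
- CTDD: percent sequence positions of the first/25%/50%/75%/100%
  occurrences of each group (195 features).
- APAAC: amphiphilic pseudo-amino acid composition, AAC plus lag-correlation
  factors of standardized hydrophobicity and hydrophilicity (20 + 2*lambda).

Unknown tokens carry no physicochemical assignment and are excluded from all
counts and normalizers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_tokenize import CANONICAL_RESIDUES, EmptyInputError

DESCRIPTOR_NAMES = ("aac", "apaac", "ctdc", "ctdd", "dde")


class TooShortError(ValueError):
    """Sequence shorter than a descriptor's minimum usable length."""


@dataclass
class DescriptorVector:
    """A named fixed-length feature vector with per-entry labels."""

    name: str
    values: np.ndarray
    feature_names: list

    def __post_init__(self) -> None:
        if len(self.values) != len(self.feature_names):
            raise ValueError("values and feature_names lengths differ")


def _clean(sequence: str) -> str:
    """Drop characters without a canonical residue assignment."""
    return "".join(ch for ch in sequence if ch in CANONICAL_RESIDUES)


# --- AAC -------------------------------------------------------------------

def aac(sequence: str) -> DescriptorVector:
    """Amino acid composition: 20 relative frequencies, alphabetical order."""
    seq = _clean(sequence)
    if not seq:
        raise EmptyInputError("aac: no canonical residues in sequence")
    n = len(seq)
    values = np.array(
        [seq.count(r) / n for r in CANONICAL_RESIDUES], dtype=float
    )
    return DescriptorVector("aac", values, [f"AAC_{r}" for r in CANONICAL_RESIDUES])


# --- DDE -------------------------------------------------------------------

#: Sense-codon counts per residue in the standard genetic code (61 total).
CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
    "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
    "T": 4, "V": 4, "W": 1, "Y": 2,
}

_N_SENSE_CODONS = 61


def dde(sequence: str) -> DescriptorVector:
    """Dipeptide deviation from expected mean (400 features).

    For dipeptide (i, j): Dc is the observed fraction over the N-1
    dipeptides; Tm = (codons_i/61)(codons_j/61) is the codon-usage
    expectation; Tv = Tm(1-Tm)/(N-1); the feature is (Dc - Tm)/sqrt(Tv).
    Dipeptides containing unknown tokens are skipped, and the normalizer
    counts only fully canonical dipeptides.
    """
    dipeps = [
        sequence[i : i + 2]
        for i in range(len(sequence) - 1)
        if sequence[i] in CODON_COUNTS and sequence[i + 1] in CODON_COUNTS
    ]
    n_pairs = len(dipeps)
    if n_pairs < 1:
        raise TooShortError(
            "dde: need at least 2 consecutive canonical residues"
        )
    counts: dict[str, int] = {}
    for dp in dipeps:
        counts[dp] = counts.get(dp, 0) + 1
    values = np.empty(400, dtype=float)
    names = []
    k = 0
    for a in CANONICAL_RESIDUES:
        pa = CODON_COUNTS[a] / _N_SENSE_CODONS
        for b in CANONICAL_RESIDUES:
            tm = pa * (CODON_COUNTS[b] / _N_SENSE_CODONS)
            tv = tm * (1.0 - tm) / n_pairs
            dc = counts.get(a + b, 0) / n_pairs
            values[k] = (dc - tm) / math.sqrt(tv)
            names.append(f"DDE_{a}{b}")
            k += 1
    return DescriptorVector("dde", values, names)


# --- CTD -------------------------------------------------------------------

# 13 physicochemical attributes, each partitioning the 20 residues into 3
# groups (iFeature group tables).
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


def ctdc(sequence: str) -> DescriptorVector:
    """Composition: per-attribute fraction of residues in each of 3 groups."""
    seq = _clean(sequence)
    if not seq:
        raise EmptyInputError("ctdc: no canonical residues in sequence")
    n = len(seq)
    values = []
    names = []
    for attr, groups in CTD_GROUPS.items():
        for g, members in enumerate(groups, start=1):
            values.append(sum(seq.count(r) for r in members) / n)
            names.append(f"CTDC_{attr}_G{g}")
    return DescriptorVector("ctdc", np.array(values, dtype=float), names)


def ctdd(sequence: str) -> DescriptorVector:
    """Distribution: percent positions of group occurrence quantiles.

    For each attribute and group, the positions (1-based, as a percentage of
    sequence length) of the 1st, 25%, 50%, 75% and 100% occurrences of that
    group's residues; 0 when the group is absent.
    """
    seq = _clean(sequence)
    if not seq:
        raise EmptyInputError("ctdd: no canonical residues in sequence")
    n = len(seq)
    values = []
    names = []
    for attr, groups in CTD_GROUPS.items():
        for g, members in enumerate(groups, start=1):
            positions = [i + 1 for i, ch in enumerate(seq) if ch in members]
            count = len(positions)
            for p in (0, 25, 50, 75, 100):
                names.append(f"CTDD_{attr}_G{g}_{p or 'first'}")
                if count == 0:
                    values.append(0.0)
                    continue
                cutoff = max(1, math.floor(p / 100 * count)) if p else 1
                values.append(100.0 * positions[cutoff - 1] / n)
    return DescriptorVector("ctdd", np.array(values, dtype=float), names)


# --- APAAC -----------------------------------------------------------------

# Tanford hydrophobicity and Hopp-Woods hydrophilicity scales.
_HYDROPHOBICITY = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}
_HYDROPHILICITY = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
    "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
    "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
    "Y": -2.3, "V": -1.5,
}


def _standardize_scale(scale: dict[str, float]) -> dict[str, float]:
    vals = np.array([scale[r] for r in CANONICAL_RESIDUES])
    mean = vals.mean()
    std = math.sqrt(((vals - mean) ** 2).mean())
    return {r: (scale[r] - mean) / std for r in CANONICAL_RESIDUES}


_H1 = _standardize_scale(_HYDROPHOBICITY)
_H2 = _standardize_scale(_HYDROPHILICITY)


def apaac(sequence: str, lam: int = 4, weight: float = 0.05) -> DescriptorVector:
    """Amphiphilic pseudo-amino acid composition (20 + 2*lam features).

    The first 20 entries are residue frequencies damped by the correlation
    mass; the remaining 2*lam entries are weighted sequence-correlation
    factors of standardized hydrophobicity and hydrophilicity at lags
    1..lam.  Requires a (canonical) sequence longer than ``lam``.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if weight <= 0:
        raise ValueError("weight must be positive")
    seq = _clean(sequence)
    n = len(seq)
    if n <= lam:
        raise TooShortError(
            f"apaac: sequence of {n} canonical residues needs length > "
            f"lambda={lam}"
        )
    h1 = np.array([_H1[ch] for ch in seq])
    h2 = np.array([_H2[ch] for ch in seq])
    thetas: list[float] = []
    for j in range(1, lam + 1):
        thetas.append(float(h1[:-j] @ h1[j:]) / (n - j))
        thetas.append(float(h2[:-j] @ h2[j:]) / (n - j))
    theta_sum = sum(thetas)
    denom = 1.0 + weight * theta_sum
    freq = np.array([seq.count(r) / n for r in CANONICAL_RESIDUES])
    values = np.concatenate(
        [freq / denom, weight * np.array(thetas, dtype=float) / denom]
    )
    names = [f"APAAC_{r}" for r in CANONICAL_RESIDUES]
    for j in range(1, lam + 1):
        names.append(f"APAAC_Pc1.{j}")
        names.append(f"APAAC_Pc2.{j}")
    return DescriptorVector("apaac", values, names)


# --- dispatch --------------------------------------------------------------

def compute_descriptor(name: str, sequence: str, **params) -> DescriptorVector:
    """Compute a descriptor by name (one of ``DESCRIPTOR_NAMES``)."""
    name = name.lower()
    if name == "aac":
        return aac(sequence)
    if name == "apaac":
        return apaac(sequence, **params)
    if name == "ctdc":
        return ctdc(sequence)
    if name == "ctdd":
        return ctdd(sequence)
    if name == "dde":
        return dde(sequence)
    raise ValueError(f"unknown descriptor {name!r}")


def featurize_records(records, name: str, **params):
    """Stack a descriptor over records into an (n, d) matrix.

    Returns (matrix, feature_names, labels-or-None).
    """
    vectors = [compute_descriptor(name, r.sequence, **params) for r in records]
    X = np.vstack([v.values for v in vectors])
    labels = None
    if all(r.label is not None for r in records):
        labels = np.array([r.label for r in records], dtype=np.int64)
    return X, vectors[0].feature_names, labels
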