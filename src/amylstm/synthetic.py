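"""Synthetic labeled protein datasets with a plantable amyloid-like signal.

Negatives are i.i.d. background sequences; positives may carry a short
planted motif (a polar-zipper-like heptapeptide by default, echoing the
QNNQQNY-style segments of real amyloidogenic proteins) at a uniform random
position, and optionally a mild compositional tilt toward hydrophobic
residues.  Signal strength is controlled by ``motif_prob`` (fraction of
positives carrying the motif) and ``composition_shift``; at
``motif_prob=0, composition_shift=0`` the two classes are exchangeable, so
any classifier's expected test AUROC is 0.5.

This generator exercises classifiers and descriptors; it is not a
biophysically realistic amyloidogenicity simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_tokenize import CANONICAL_RESIDUES, ProteinRecord, write_fasta

#: Residues treated as hydrophobic for the compositional tilt.
HYDROPHOBIC_RESIDUES = "AVLIMFWC"

DEFAULT_MOTIF = "QNNQQNY"


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    ``background`` is a 20-vector of residue frequencies (uniform by
    default); lengths are uniform over ``length_range``.
    """

    n_pos: int = 150
    n_neg: int = 380
    length_range: tuple = (30, 200)
    motif: str = DEFAULT_MOTIF
    motif_prob: float = 1.0
    background: Optional[np.ndarray] = None
    composition_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background is None:
            self.background = np.full(20, 1.0 / 20)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,):
            raise ValueError("background must have 20 entries")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if not 0.0 <= self.motif_prob <= 1.0:
            raise ValueError("motif_prob must lie in [0, 1]")
        if self.composition_shift < 0:
            raise ValueError("composition_shift must be >= 0")
        if any(ch not in CANONICAL_RESIDUES for ch in self.motif):
            raise ValueError(
                f"motif {self.motif!r} contains non-canonical residues"
            )
        lo, hi = self.length_range
        if lo < len(self.motif):
            raise ValueError(
                f"minimum length {lo} is shorter than the motif "
                f"({len(self.motif)} residues)"
            )
        if hi < lo:
            raise ValueError("length_range must be (min, max) with max >= min")


def _positive_background(config: SynthConfig) -> np.ndarray:
    """Background tilted toward hydrophobic residues by composition_shift."""
    w = config.background * np.exp(
        config.composition_shift
        * np.array([ch in HYDROPHOBIC_RESIDUES for ch in CANONICAL_RESIDUES])
    )
    return w / w.sum()


def generate(config: SynthConfig) -> list[ProteinRecord]:
    """Generate labeled records: positives first, then negatives.

    Fully determined by ``config.seed``: same config -> identical records.
    """
    rng = np.random.default_rng(config.seed)
    residues = np.array(list(CANONICAL_RESIDUES))
    lo, hi = config.length_range
    pos_bg = _positive_background(config)
    records: list[ProteinRecord] = []
    for k in range(config.n_pos):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(residues, size=length, p=pos_bg))
        if rng.random() < config.motif_prob:
            start = int(rng.integers(0, length - len(config.motif) + 1))
            seq[start:start + len(config.motif)] = list(config.motif)
        records.append(
            ProteinRecord(id=f"pos_{k + 1:04d}", sequence="".join(seq), label=1)
        )
    for k in range(config.n_neg):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(residues, size=length, p=config.background)
        records.append(
            ProteinRecord(id=f"neg_{k + 1:04d}", sequence="".join(seq), label=0)
        )
    return records


def write_dataset(records, out_dir) -> tuple[Path, Path]:
    """Write pos.fasta / neg.fasta under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos_path = out_dir / "pos.fasta"
    neg_path = out_dir / "neg.fasta"
    write_fasta([r for r in records if r.label == 1], pos_path)
    write_fasta([r for r in records if r.label == 0], neg_path)
    return pos_path, neg_path
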