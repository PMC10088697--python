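"""Synthetic peptide datasets with planted compositional class structure.

The generator emulates the benchmark's shape — short peptides (8-35
residues, uniform lengths) and a roughly 1:9 class imbalance — with a
planted signal that lives in residue frequencies: positive-class peptides
draw a chosen set of residues with probability elevated by ``effect_size``
(shared equally across the set, remaining mass renormalized over the other
letters), negatives are uniform. Because amino-acid-composition features
have closed-form expectations under this model, recovery assertions are
exact: with effect size e on residue H, the expected AAC_H gap between
classes is 100*e percentage points. Everything is seed-deterministic.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .sequences import ALPHABET, Peptide, write_fasta


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted benchmark fixture.

    Defaults give a miniature imbalanced benchmark (60 positives / 540
    negatives, mimicking the 313:2908 benchmark ratio) with the signal
    planted on histidine at effect size 0.3.
    """

    n_pos: int = 60
    n_neg: int = 540
    length_range: Tuple[int, int] = (8, 35)
    biased_residues: FrozenSet[str] = frozenset({"H"})
    effect_size: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class counts must be >= 1")
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect_size must lie in [0, 1]")
        if not self.biased_residues <= set(ALPHABET):
            raise ValueError("biased_residues must be canonical amino acids")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length_range")


def _draw_peptides(
    n: int,
    length_range: Tuple[int, int],
    probs: np.ndarray,
    rng: np.random.Generator,
    prefix: str,
) -> List[Peptide]:
    lo, hi = length_range
    letters = np.array(list(ALPHABET))
    out: List[Peptide] = []
    for i in range(1, n + 1):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(letters[rng.choice(20, size=L, p=probs)])
        out.append(Peptide(id=f"{prefix}{i}", sequence=seq))
    return out


def random_peptides(
    n: int,
    length_range: Tuple[int, int] = (8, 35),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    prefix: str = "seq_",
) -> List[Peptide]:
    """n i.i.d. uniform-residue peptides with lengths uniform on the range."""
    if n < 0:
        raise ValueError("n must be >= 0")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid length_range")
    rng = rng if rng is not None else np.random.default_rng(seed)
    return _draw_peptides(n, length_range, np.full(20, 0.05), rng, prefix)


def class_probabilities(spec: FixtureSpec) -> Tuple[np.ndarray, np.ndarray]:
    """(positive, negative) residue-probability vectors of the planted model."""
    neg = np.full(20, 0.05)
    pos = neg.copy()
    biased = sorted(spec.biased_residues)
    if biased and spec.effect_size > 0:
        bump = spec.effect_size / len(biased)
        idx = [ALPHABET.index(r) for r in biased]
        pos[idx] += bump
        rest = [i for i in range(20) if i not in idx]
        remaining = 1.0 - pos[idx].sum()
        if remaining < 0:
            raise ValueError("effect_size pushes probabilities above 1")
        pos[rest] = remaining / len(rest)
    return pos, neg


def planted_dataset(spec: FixtureSpec) -> Tuple[List[Peptide], np.ndarray]:
    """Peptides plus aligned 0/1 labels (positives first)."""
    rng = np.random.default_rng(spec.seed)
    p_pos, p_neg = class_probabilities(spec)
    pos = _draw_peptides(spec.n_pos, spec.length_range, p_pos, rng, "pos_")
    neg = _draw_peptides(spec.n_neg, spec.length_range, p_neg, rng, "neg_")
    labels = np.array([1] * spec.n_pos + [0] * spec.n_neg)
    return pos + neg, labels


def fixture_benchmark(spec: FixtureSpec, outdir: str | os.PathLike) -> dict:
    """Write a miniature benchmark to disk: positive/negative FASTA plus a
    manifest of the planted parameters. Returns the written paths."""
    os.makedirs(outdir, exist_ok=True)
    peptides, labels = planted_dataset(spec)
    pos = [p for p, y in zip(peptides, labels) if y == 1]
    neg = [p for p, y in zip(peptides, labels) if y == 0]
    paths = {
        "positive": os.path.join(outdir, "positive.fasta"),
        "negative": os.path.join(outdir, "negative.fasta"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    write_fasta(pos, paths["positive"])
    write_fasta(neg, paths["negative"])
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "n_pos": spec.n_pos,
                "n_neg": spec.n_neg,
                "length_range": list(spec.length_range),
                "biased_residues": sorted(spec.biased_residues),
                "effect_size": spec.effect_size,
                "seed": spec.seed,
            },
            fh,
            indent=2,
        )
    return paths
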