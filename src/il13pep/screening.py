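"""Apply a trained model to new peptides: predict, design, protein scan.

The decision rule is the published webserver convention: a peptide is called
IL-13 inducing iff its positive-class probability is >= 0.06 (the default,
overridable threshold). The *design* operation enumerates all 19L
single-residue substitution mutants of an L-mer; the *scan* operation
enumerates all overlapping fixed-length windows of a protein (default 15,
the length of the published case-study peptides). Coordinates in reports
are 1-based, matching protein-mutation naming such as A570D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from typing import List, Optional, Sequence, Union

from .features import EncodingError, encode_batch
from .models import TrainedModel
from .sequences import ALPHABET, Peptide, validate_peptide

DEFAULT_THRESHOLD = 0.06
DEFAULT_WINDOW = 15

POSITIVE_LABEL = "IL-13"
NEGATIVE_LABEL = "non-IL-13"


@dataclass(frozen=True)
class ScreenResult:
    peptide: Peptide
    score: float
    label: str
    threshold: float
    provenance: str = "input"
    error: Optional[str] = None


def _label(score: float, threshold: float) -> str:
    return POSITIVE_LABEL if score >= threshold else NEGATIVE_LABEL


def predict(
    model: TrainedModel,
    peptides: Sequence[Union[Peptide, str]],
    threshold: float = DEFAULT_THRESHOLD,
    catalog=None,
    provenances: Optional[Sequence[str]] = None,
) -> List[ScreenResult]:
    """Score peptides and call IL-13 induction at ``score >= threshold``.

    A peptide that cannot be encoded yields a per-peptide error entry; the
    run continues for the rest.
    """
    results: List[ScreenResult] = []
    peps = [
        p if isinstance(p, Peptide) else validate_peptide(p, id=f"seq_{i}")
        for i, p in enumerate(peptides, 1)
    ]
    provs = list(provenances) if provenances is not None else ["input"] * len(peps)
    for p, prov in zip(peps, provs):
        try:
            score = float(np.asarray(model.predict_proba(encode_batch([p]))).reshape(-1)[0])
        except EncodingError as exc:
            results.append(
                ScreenResult(p, float("nan"), "error", threshold, prov, str(exc))
            )
            continue
        results.append(ScreenResult(p, score, _label(score, threshold), threshold, prov))
    return results


def design_mutants(p: Union[Peptide, str]) -> List[Peptide]:
    """All 19 x length single-residue substitution mutants of ``p``.

    Position-major, substitute-residue-alphabetical order; each mutant has
    Hamming distance exactly 1 from the parent; the parent is excluded.
    Mutant ids append the ``<from><pos><to>`` mutation name.
    """
    if isinstance(p, str):
        p = validate_peptide(p)
    mutants: List[Peptide] = []
    for pos, ref in enumerate(p.sequence, start=1):
        for alt in ALPHABET:
            if alt == ref:
                continue
            seq = p.sequence[: pos - 1] + alt + p.sequence[pos:]
            mutants.append(Peptide(id=f"{p.id}_{ref}{pos}{alt}", sequence=seq))
    return mutants


def scan_protein(
    protein: Union[Peptide, str], window: int = DEFAULT_WINDOW
) -> List[Peptide]:
    """All overlapping windows of ``protein`` (stride 1, 1-based starts).

    A protein of length N yields N - window + 1 peptides.
    """
    if isinstance(protein, str):
        protein = validate_peptide(protein, id="protein")
    if protein.length < window:
        raise ValueError(
            f"protein length {protein.length} shorter than window {window}"
        )
    return [
        Peptide(
            id=f"{protein.id}_w{start}",
            sequence=protein.sequence[start - 1 : start - 1 + window],
        )
        for start in range(1, protein.length - window + 2)
    ]


def screen_mutants(
    model: TrainedModel,
    p: Union[Peptide, str],
    threshold: float = DEFAULT_THRESHOLD,
) -> List[ScreenResult]:
    """Score every single-residue mutant of ``p``."""
    if isinstance(p, str):
        p = validate_peptide(p)
    mutants = design_mutants(p)
    provs = [m.id.rsplit("_", 1)[-1] for m in mutants]
    return predict(model, mutants, threshold=threshold, provenances=provs)


def screen_protein(
    model: TrainedModel,
    protein: Union[Peptide, str],
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
) -> List[ScreenResult]:
    """Score every overlapping window of ``protein``."""
    windows = scan_protein(protein, window)
    provs = [
        f"window:{i}-{i + window - 1}" for i in range(1, len(windows) + 1)
    ]
    return predict(model, windows, threshold=threshold, provenances=provs)


def screen_report(results: Sequence[ScreenResult], path: str) -> None:
    """Write a screening report TSV (scores printed to 2 decimals)."""
    if not results:
        raise ValueError("no results to report")
    with open(path, "w") as fh:
        fh.write("id\tsequence\tprovenance\tscore\tlabel\n")
        for r in results:
            score = "NA" if r.error else f"{r.score:.2f}"
            fh.write(
                f"{r.peptide.id}\t{r.peptide.sequence}\t{r.provenance}\t"
                f"{score}\t{r.label}\n"
            )
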