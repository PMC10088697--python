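"""Composition-based peptide descriptors and the sklearn-style encoder.

Every family maps a peptide sequence to a fixed-length named block; the
concatenation over the catalog's families is the 9151-dimensional feature
vector. Percentage families (AAC/DPC/TPC/ATC/PCP/CTC and the per-attribute
CeTD composition block) each sum to 100 for any valid peptide. Encoding is a
pure function of the sequence: identical input gives bit-identical output.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .catalog import ATOMS, BOND_KINDS, CTD_QUANTILES, FeatureCatalog, load_catalog
from .sequences import ALPHABET, Peptide, validate_peptide

_RES_INDEX = {r: i for i, r in enumerate(ALPHABET)}

#: Minimum length for which the full catalog is defined (TPC and CTC use
#: 3-residue windows). Shorter peptides are rejected, not zero-filled.
MIN_ENCODE_LENGTH = 3


class EncodingError(ValueError):
    """Peptide cannot be encoded (e.g. shorter than a family's window)."""


def _as_peptide(p: Union[Peptide, str], idx: int = 1) -> Peptide:
    if isinstance(p, Peptide):
        return p
    return validate_peptide(p, id=f"seq_{idx}")


def _codes(p: Peptide) -> np.ndarray:
    return np.fromiter((_RES_INDEX[r] for r in p.sequence), dtype=np.int64)


# ---------------------------------------------------------------------------
# family computations (raw numpy blocks, catalog-order aligned)

def _kmer_block(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.size - k + 1
    if n < 1:
        raise EncodingError(f"{k}-mer composition undefined for length {codes.size}")
    idx = np.zeros(n, dtype=np.int64)
    for j in range(k):
        idx = idx * 20 + codes[j : j + n]
    return 100.0 * np.bincount(idx, minlength=20 ** k) / n


def _atc_block(codes: np.ndarray, chem: Dict[str, Dict[str, int]]) -> np.ndarray:
    counts = np.zeros(len(ATOMS))
    per_res = np.array([[chem[r][a] for a in ATOMS] for r in ALPHABET], float)
    counts = np.bincount(codes, minlength=20) @ per_res
    return 100.0 * counts / counts.sum()


def _btc_block(codes: np.ndarray, chem: Dict[str, Dict[str, int]]) -> np.ndarray:
    per_res = np.array(
        [[chem[r][f"bonds_{k}"] for k in BOND_KINDS] for r in ALPHABET], float
    )
    return np.bincount(codes, minlength=20) @ per_res


def _pcp_block(codes: np.ndarray, groups: Dict[str, str]) -> np.ndarray:
    member = np.array(
        [[1.0 if r in residues else 0.0 for r in ALPHABET]
         for residues in groups.values()]
    )
    freq = np.bincount(codes, minlength=20) / codes.size
    return 100.0 * member @ freq


def _ser_block(codes: np.ndarray) -> np.ndarray:
    f = np.bincount(codes, minlength=20) / codes.size
    out = np.zeros(20)
    nz = f > 0
    out[nz] = -f[nz] * np.log2(f[nz])
    return out


def _rri_block(codes: np.ndarray) -> np.ndarray:
    # sum of squared maximal-run lengths per residue type, scaled by 1/L^2
    out = np.zeros(20)
    L = codes.size
    start = 0
    for i in range(1, L + 1):
        if i == L or codes[i] != codes[start]:
            out[codes[start]] += (i - start) ** 2
            start = i
    return 100.0 * out / (L * L)


def _ddr_block(codes: np.ndarray) -> np.ndarray:
    # mean gap between consecutive occurrences, as % of length; 0 if < 2 hits
    out = np.zeros(20)
    L = codes.size
    for r in range(20):
        pos = np.flatnonzero(codes == r)
        if pos.size >= 2:
            out[r] = 100.0 * np.diff(pos).mean() / L
    return out


def _ctc_block(codes: np.ndarray, classes: Dict[str, int]) -> np.ndarray:
    n = codes.size - 2
    if n < 1:
        raise EncodingError(f"conjoint triads undefined for length {codes.size}")
    cls = np.array([classes[ALPHABET[c]] - 1 for c in codes], dtype=np.int64)
    idx = cls[:-2] * 49 + cls[1:-1] * 7 + cls[2:]
    return 100.0 * np.bincount(idx, minlength=343) / n


def _ctd_block(codes: np.ndarray, groups: Dict[str, Dict[str, int]]) -> np.ndarray:
    L = codes.size
    out: List[float] = []
    for attr, mapping in groups.items():
        g = np.array([mapping[ALPHABET[c]] for c in codes], dtype=np.int64)
        # composition (%) of the three groups
        comp = 100.0 * np.bincount(g, minlength=4)[1:] / L
        out.extend(comp)
        # transitions: % of adjacent pairs crossing each unordered group pair
        a, b = g[:-1], g[1:]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        denom = max(L - 1, 1)
        for p, q in ((1, 2), (1, 3), (2, 3)):
            out.append(100.0 * np.count_nonzero((lo == p) & (hi == q)) / denom)
        # distribution: positions of group members at sequence quantiles
        pos_feats: List[float] = []
        cnt_feats: List[float] = []
        for grp in (1, 2, 3):
            pos = np.flatnonzero(g == grp) + 1  # 1-based
            n = pos.size
            for q in CTD_QUANTILES:
                if n == 0:
                    pos_feats.append(0.0)
                else:
                    k = max(1, math.ceil(q / 100.0 * n))
                    pos_feats.append(100.0 * pos[k - 1] / L)
            for q in CTD_QUANTILES:
                window = max(1, math.ceil(q / 100.0 * L))
                cnt_feats.append(float(np.count_nonzero(pos <= window)))
        out.extend(pos_feats)
        out.extend(cnt_feats)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# public per-family operations (named vectors)

def kmer_composition(p: Union[Peptide, str], k: int) -> pd.Series:
    """Overlapping k-mer composition (%) for k in {1, 2, 3}; sums to 100."""
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    p = _as_peptide(p)
    prefix = {1: "AAC", 2: "DPC", 3: "TPC"}[k]
    import itertools

    names = [
        f"{prefix}_{''.join(t)}"
        for t in itertools.product(ALPHABET, repeat=k)
    ]
    return pd.Series(_kmer_block(_codes(p), k), index=names, name=p.id)


def shannon_entropy_residue(p: Union[Peptide, str]) -> pd.Series:
    """Per-residue-type Shannon entropy SER_r = -f_r log2 f_r (bits)."""
    p = _as_peptide(p)
    return pd.Series(
        _ser_block(_codes(p)), index=[f"SER_{a}" for a in ALPHABET], name=p.id
    )


def sequence_entropy(p: Union[Peptide, str]) -> float:
    """Whole-sequence Shannon entropy (bits); equals the sum of SER values."""
    p = _as_peptide(p)
    return float(_ser_block(_codes(p)).sum())


def bond_composition(p: Union[Peptide, str], catalog: FeatureCatalog | None = None) -> pd.Series:
    """Total / hydrogen / single / double bond counts summed over residues."""
    p = _as_peptide(p)
    catalog = catalog or default_catalog()
    block = _btc_block(_codes(p), catalog.params["chemistry"])
    return pd.Series(block, index=[f"BTC_{k}" for k in BOND_KINDS], name=p.id)


def ctd_features(p: Union[Peptide, str], catalog: FeatureCatalog | None = None) -> pd.Series:
    """Composition/transition/distribution vector over the 8 CTD attributes."""
    p = _as_peptide(p)
    catalog = catalog or default_catalog()
    names = next(f.names for f in catalog.families if f.code == "CeTD")
    return pd.Series(
        _ctd_block(_codes(p), catalog.params["ctd_groups"]),
        index=list(names), name=p.id,
    )


def conjoint_triad(p: Union[Peptide, str], catalog: FeatureCatalog | None = None) -> pd.Series:
    """Conjoint-triad class composition (343 bins, %); sums to 100."""
    p = _as_peptide(p)
    catalog = catalog or default_catalog()
    names = next(f.names for f in catalog.families if f.code == "CTC")
    return pd.Series(
        _ctc_block(_codes(p), catalog.params["ctc_classes"]),
        index=list(names), name=p.id,
    )


# ---------------------------------------------------------------------------
# full-catalog encoding

_DEFAULT_CATALOG: FeatureCatalog | None = None


def default_catalog() -> FeatureCatalog:
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = load_catalog()
    return _DEFAULT_CATALOG


def _encode_codes(codes: np.ndarray, catalog: FeatureCatalog) -> np.ndarray:
    if codes.size < MIN_ENCODE_LENGTH:
        raise EncodingError(
            f"peptide of length {codes.size} shorter than the minimum "
            f"encodable length {MIN_ENCODE_LENGTH}"
        )
    params = catalog.params
    blocks: List[np.ndarray] = []
    for fam in catalog.families:
        if fam.code == "AAC":
            blocks.append(_kmer_block(codes, 1))
        elif fam.code == "DPC":
            blocks.append(_kmer_block(codes, 2))
        elif fam.code == "TPC":
            blocks.append(_kmer_block(codes, 3))
        elif fam.code == "ATC":
            blocks.append(_atc_block(codes, params["chemistry"]))
        elif fam.code == "BTC":
            blocks.append(_btc_block(codes, params["chemistry"]))
        elif fam.code == "PCP":
            blocks.append(_pcp_block(codes, params["pcp_groups"]))
        elif fam.code == "SER":
            blocks.append(_ser_block(codes))
        elif fam.code == "SE":
            blocks.append(np.array([_ser_block(codes).sum()]))
        elif fam.code == "RRI":
            blocks.append(_rri_block(codes))
        elif fam.code == "DDR":
            blocks.append(_ddr_block(codes))
        elif fam.code == "CTC":
            blocks.append(_ctc_block(codes, params["ctc_classes"]))
        elif fam.code == "CeTD":
            blocks.append(_ctd_block(codes, params["ctd_groups"]))
        else:  # pragma: no cover - guarded by catalog validation
            raise EncodingError(f"no encoder for family {fam.code!r}")
    vec = np.concatenate(blocks)
    if not np.all(np.isfinite(vec)):
        raise EncodingError("non-finite feature value")
    return vec


def encode(p: Union[Peptide, str], catalog: FeatureCatalog | None = None) -> pd.Series:
    """Encode one peptide into the full named feature vector (length 9151)."""
    p = _as_peptide(p)
    catalog = catalog or default_catalog()
    return pd.Series(_encode_codes(_codes(p), catalog), index=catalog.names, name=p.id)


def encode_batch(
    peptides: Sequence[Union[Peptide, str]],
    catalog: FeatureCatalog | None = None,
) -> pd.DataFrame:
    """Encode peptides into a feature table (rows follow input order).

    Any encoding failure aborts with the offending peptide's id.
    """
    catalog = catalog or default_catalog()
    rows, ids = [], []
    for i, raw in enumerate(peptides, 1):
        p = _as_peptide(raw, i)
        try:
            rows.append(_encode_codes(_codes(p), catalog))
        except EncodingError as exc:
            raise EncodingError(f"peptide {p.id!r}: {exc}") from exc
        ids.append(p.id)
    data = np.vstack(rows) if rows else np.empty((0, catalog.total_dim))
    return pd.DataFrame(data, index=ids, columns=catalog.names)


class PeptideEncoder(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: peptides -> 9151-dim feature matrix.

    Parameters
    ----------
    catalog : FeatureCatalog or None
        Descriptor catalog; ``None`` uses the bundled 9151-feature manifest.

    Examples
    --------
    >>> PeptideEncoder().fit_transform(["ELDSFKEELDKYFKN"]).shape
    (1, 9151)
    """

    def __init__(self, catalog: FeatureCatalog | None = None):
        self.catalog = catalog

    def fit(self, X: Sequence, y=None) -> "PeptideEncoder":
        self.catalog_ = self.catalog or default_catalog()
        self.feature_names_out_ = np.asarray(self.catalog_.names, dtype=object)
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[Union[Peptide, str]]) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "catalog_")
        return encode_batch(list(X), self.catalog_).to_numpy()

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "catalog_")
        return self.feature_names_out_

    def _more_tags(self):  # pragma: no cover
        return {"X_types": ["string"], "no_validation": True}
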