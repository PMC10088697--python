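"""The named 9151-dimensional composition descriptor space.

The catalog enumerates twelve descriptor families computed from a peptide's
sequence alone: k-mer compositions (AAC/DPC/TPC), atom and bond composition
(ATC/BTC), physicochemical-class composition (PCP), Shannon entropies
(SER/SE), residue-repeat and residue-spacing summaries (RRI/DDR), conjoint
triads (CTC), and composition/transition/distribution descriptors over
three-group physicochemical partitions (CeTD). Family dimensions and the
constant residue tables are bundled as plain TSV data files; the hard
contract is that the dims sum to exactly 9151 and feature names are unique.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Sequence, Tuple

from .sequences import ALPHABET

TOTAL_DIM = 9151

#: Feature names that must be present in any valid catalog (the ten most
#: discriminative features reported for this predictor).
REQUIRED_NAMES = (
    "BTC_S",
    "CeTD_SS1",
    "TPC_RQF",
    "SER_I",
    "SER_L",
    "SER_T",
    "BTC_T",
    "CeTD_75_p_HB1",
    "AAC_H",
    "SER_P",
)

ATOMS = ("C", "H", "N", "O", "S")
BOND_KINDS = ("T", "H", "S", "D")
CTD_QUANTILES = (0, 25, 50, 75, 100)


class CatalogError(ValueError):
    """Inconsistent descriptor-family manifest."""


def _read_table(name: str) -> List[List[str]]:
    text = (
        resources.files("il13pep.data").joinpath(name).read_text()
    )
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows[1:]  # drop header


def _load_residue_chemistry() -> Dict[str, Dict[str, int]]:
    table: Dict[str, Dict[str, int]] = {}
    for res, c, h, n, o, s, rings, dbl in _read_table("residue_chemistry.tsv"):
        atoms = dict(C=int(c), H=int(h), N=int(n), O=int(o), S=int(s))
        n_atoms = sum(atoms.values())
        total = n_atoms - 1 + int(rings)
        table[res] = {
            **atoms,
            "bonds_T": total,
            "bonds_H": atoms["H"],
            "bonds_S": total - int(dbl),
            "bonds_D": int(dbl),
        }
    return table


def _load_ctd_groups() -> Dict[str, Dict[str, int]]:
    """attribute -> residue -> group (1..3)."""
    groups: Dict[str, Dict[str, int]] = {}
    for attr, grp, residues in _read_table("ctd_groups.tsv"):
        groups.setdefault(attr, {})
        for r in residues:
            groups[attr][r] = int(grp)
    for attr, mapping in groups.items():
        if sorted(mapping) != sorted(ALPHABET):
            raise CatalogError(f"CTD attribute {attr}: not a partition of the alphabet")
    return groups


def _load_ctc_classes() -> Dict[str, int]:
    classes: Dict[str, int] = {}
    for cls, residues in _read_table("ctc_classes.tsv"):
        for r in residues:
            classes[r] = int(cls)
    if sorted(classes) != sorted(ALPHABET):
        raise CatalogError("CTC classes do not partition the alphabet")
    return classes


def _load_pcp_groups() -> Dict[str, str]:
    return {code: residues for code, residues, _ in _read_table("pcp_groups.tsv")}


def _family_names(code: str, params: Mapping) -> List[str]:
    if code == "AAC":
        return [f"AAC_{a}" for a in ALPHABET]
    if code == "DPC":
        return [f"DPC_{a}{b}" for a, b in itertools.product(ALPHABET, repeat=2)]
    if code == "TPC":
        return [
            f"TPC_{a}{b}{c}"
            for a, b, c in itertools.product(ALPHABET, repeat=3)
        ]
    if code == "ATC":
        return [f"ATC_{a}" for a in ATOMS]
    if code == "BTC":
        return [f"BTC_{k}" for k in BOND_KINDS]
    if code == "PCP":
        return list(params["pcp_groups"])
    if code == "SER":
        return [f"SER_{a}" for a in ALPHABET]
    if code == "SE":
        return ["SE"]
    if code == "RRI":
        return [f"RRI_{a}" for a in ALPHABET]
    if code == "DDR":
        return [f"DDR_{a}" for a in ALPHABET]
    if code == "CTC":
        return [
            f"CTC_{i}{j}{k}"
            for i, j, k in itertools.product("1234567", repeat=3)
        ]
    if code == "CeTD":
        names: List[str] = []
        for attr in params["ctd_attributes"]:
            names += [f"CeTD_{attr}{g}" for g in (1, 2, 3)]
            names += [f"CeTD_{attr}_T{p}" for p in ("12", "13", "23")]
            for g in (1, 2, 3):
                names += [f"CeTD_{q}_{attr}{g}" for q in CTD_QUANTILES]
            for g in (1, 2, 3):
                names += [f"CeTD_{q}_p_{attr}{g}" for q in CTD_QUANTILES]
        return names
    raise CatalogError(f"unknown descriptor family {code!r}")


@dataclass(frozen=True)
class DescriptorFamily:
    """One descriptor family: short code, dimension, and feature names."""

    code: str
    dim: int
    names: Tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise CatalogError(f"family {self.code}: dim must be >= 1")
        if len(self.names) != self.dim:
            raise CatalogError(
                f"family {self.code}: manifest dim {self.dim} != "
                f"{len(self.names)} generated feature names"
            )


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered descriptor families plus the bundled constant tables."""

    families: Tuple[DescriptorFamily, ...]
    params: Mapping = field(repr=False)

    @property
    def total_dim(self) -> int:
        return sum(f.dim for f in self.families)

    @property
    def names(self) -> List[str]:
        return [n for f in self.families for n in f.names]

    def slices(self) -> Dict[str, slice]:
        """Family code -> slice of the concatenated feature vector."""
        out, start = {}, 0
        for f in self.families:
            out[f.code] = slice(start, start + f.dim)
            start += f.dim
        return out


def _read_manifest(path: str | None) -> List[Tuple[str, int, str]]:
    if path is None:
        rows = _read_table("families.tsv")
    else:
        with open(path) as fh:
            lines = [
                ln.strip() for ln in fh
                if ln.strip() and not ln.startswith("#")
            ]
        rows = [ln.split("\t") for ln in lines[1:]]
    return [(code, int(dim), desc) for code, dim, desc in rows]


def load_catalog(manifest: str | None = None) -> FeatureCatalog:
    """Load and validate the descriptor catalog.

    ``manifest`` is a path to an alternative family manifest (TSV with
    ``family / dim / description`` columns); ``None`` loads the bundled one.
    Raises :class:`CatalogError` if the family dims do not sum to 9151 or
    feature names collide.
    """
    params = {
        "chemistry": _load_residue_chemistry(),
        "ctd_groups": _load_ctd_groups(),
        "ctd_attributes": tuple(_load_ctd_groups().keys()),
        "ctc_classes": _load_ctc_classes(),
        "pcp_groups": _load_pcp_groups(),
    }
    families = tuple(
        DescriptorFamily(code, dim, tuple(_family_names(code, params)), desc)
        for code, dim, desc in _read_manifest(manifest)
    )
    catalog = FeatureCatalog(families=families, params=params)
    if catalog.total_dim != TOTAL_DIM:
        raise CatalogError(
            f"catalog dimension mismatch: expected {TOTAL_DIM}, "
            f"got {catalog.total_dim}"
        )
    names = catalog.names
    if len(set(names)) != len(names):
        raise CatalogError("duplicate feature names in catalog")
    return catalog
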