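"""Diagnosis-code mappings: CCS condition grouping and Quan comorbidity categories.

Diagnosis codes are opaque strings; no ICD revision is hard-coded. A mapping
file is a CSV with columns ``code,category`` (CCS kind) or
``code,category,weight`` (Quan kind). A trailing ``*`` marks a prefix entry —
``I21*`` matches any code starting with ``I21`` — and exact entries always
take precedence over prefix entries; among prefix entries the longest match
wins.

Two mappings ship with the package: ``quan_charlson.csv``, a transcription of
the standard 17-category Quan ICD-10 comorbidity coding algorithm with the
original Charlson weights, and ``ccs_toy.csv``, a small crosswalk covering the
condition groups the bundled reports use. Real analyses should load the full
official CCS crosswalk via :func:`load_code_mapping`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

#: Category scored only when the severe partner is absent → severe partner.
#: (mild/severe liver disease, diabetes without/with chronic complication,
#: any malignancy / metastatic solid tumour)
QUAN_HIERARCHY: dict[str, str] = {
    "mild_liver_disease": "moderate_severe_liver_disease",
    "diabetes_without_complication": "diabetes_with_complication",
    "any_malignancy": "metastatic_solid_tumour",
}

UNCLASSIFIED = "Residual codes; unclassified"


class MappingError(ValueError):
    """Malformed or self-contradictory code-mapping file."""


@dataclass
class CodeMapping:
    """Diagnosis-code → category mapping with optional category weights."""

    exact: dict[str, str] = field(default_factory=dict)
    prefixes: list[tuple[str, str]] = field(default_factory=list)
    weights: dict[str, int] = field(default_factory=dict)
    hierarchy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # longest prefix first so the most specific prefix wins
        self.prefixes = sorted(self.prefixes, key=lambda t: -len(t[0]))
        partners = list(self.hierarchy.keys()) + list(self.hierarchy.values())
        if len(partners) != len(set(partners)):
            raise MappingError("a category appears in more than one hierarchy pair")

    def lookup(self, code: str) -> str | None:
        """Category for ``code``, or None if unmapped."""
        hit = self.exact.get(code)
        if hit is not None:
            return hit
        for prefix, category in self.prefixes:
            if code.startswith(prefix):
                return category
        return None

    def map_series(self, codes: pd.Series, default: str | None = None) -> pd.Series:
        """Vectorised lookup over a code Series (cached per unique code)."""
        uniq = codes.dropna().unique()
        table = {c: (self.lookup(str(c)) or default) for c in uniq}
        return codes.map(table)

    @property
    def categories(self) -> set[str]:
        return set(self.exact.values()) | {c for _, c in self.prefixes}


def load_code_mapping(path: str | Path, kind: str) -> CodeMapping:
    """Load a mapping CSV of the given kind (``"ccs"`` or ``"quan"``)."""
    if kind not in ("ccs", "quan"):
        raise ValueError(f"kind must be 'ccs' or 'quan', got {kind!r}")
    want = ["code", "category"] + (["weight"] if kind == "quan" else [])
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise MappingError(f"{path}: missing column(s) {missing}")

    exact: dict[str, str] = {}
    prefixes: dict[str, str] = {}
    weights: dict[str, int] = {}
    for row in df.itertuples(index=False):
        code = str(row.code).strip()
        category = str(row.category).strip()
        target = prefixes if code.endswith("*") else exact
        key = code.rstrip("*")
        if key in target and target[key] != category:
            raise MappingError(
                f"{path}: code {code!r} mapped to both {target[key]!r} and {category!r}"
            )
        target[key] = category
        if kind == "quan":
            w = int(row.weight)
            if weights.setdefault(category, w) != w:
                raise MappingError(f"{path}: conflicting weights for {category!r}")
    hierarchy = (
        {m: s for m, s in QUAN_HIERARCHY.items() if m in weights and s in weights}
        if kind == "quan"
        else {}
    )
    return CodeMapping(
        exact=exact,
        prefixes=list(prefixes.items()),
        weights=weights,
        hierarchy=hierarchy,
    )


def _data_path(name: str) -> Path:
    return Path(str(resources.files("husegment").joinpath("data", name)))


def packaged_quan_mapping() -> CodeMapping:
    """The bundled 17-category Quan comorbidity mapping (original weights)."""
    return load_code_mapping(_data_path("quan_charlson.csv"), kind="quan")


def packaged_ccs_mapping() -> CodeMapping:
    """The bundled toy CCS crosswalk (reporting categories only)."""
    return load_code_mapping(_data_path("ccs_toy.csv"), kind="ccs")
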