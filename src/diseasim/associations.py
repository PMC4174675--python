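"""Disease-gene association tables and their mapping to 3-digit ICD-9 codes.

Source vocabularies (OMIM ids, MeSH terms, DO ids, UMLS CUIs) are mapped to
ICD-9 through a user-supplied table; codes are truncated to the 3-digit
level (E/V-prefixed codes keep their letter) and gene sets of diseases that
collapse onto the same code are unioned.  Gene identifiers are opaque,
case-sensitive strings.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "load_associations",
    "load_id_mapping",
    "truncate_icd9",
    "to_icd9",
    "filter_min_genes",
    "remove_pleiotropic",
    "degree_distribution",
    "combine_maps",
    "write_disease_gene_map",
    "read_disease_gene_map",
    "MappingReport",
]

_ICD9_RE = re.compile(r"^(E|V)?\d{1,3}(\.\d{1,2})?$")

#: A disease-gene map is a plain dict: 3-digit ICD-9 code -> set of gene ids.
DiseaseGeneMap = dict


@dataclass
class MappingReport:
    """Book-keeping from :func:`to_icd9`: which source ids were dropped."""

    n_pairs_in: int = 0
    n_pairs_mapped: int = 0
    unmapped_ids: set = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_pairs_in": self.n_pairs_in,
                "n_pairs_mapped": self.n_pairs_mapped,
                "unmapped_ids": sorted(self.unmapped_ids),
            },
            indent=2,
        )


def load_associations(path) -> list[tuple[str, str]]:
    """Read a (disease_id, gene_id) TSV; duplicates are preserved here and
    only collapse later, at the union-merge stage."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: expected disease_id<TAB>gene_id")
            pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        warnings.warn(f"{path}: empty association file")
    return pairs


def load_id_mapping(path) -> dict[str, set[str]]:
    """Read a (source_id, icd9_code) TSV into source id -> set of codes."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str).iloc[:, :2]
    df.columns = ["source_id", "icd9"]
    mapping: dict[str, set[str]] = {}
    for source, code in zip(df["source_id"], df["icd9"]):
        if pd.isna(source) or pd.isna(code) or not str(code).strip():
            raise ValueError(f"{path}: mapping row with empty target ({source!r} -> {code!r})")
        mapping.setdefault(str(source).strip(), set()).add(str(code).strip())
    return mapping


def truncate_icd9(code: str) -> str:
    """Truncate an ICD-9 code to the category (3-digit) level.

    Numeric codes keep their first three digits (zero-padded); E codes keep
    the letter plus three digits, V codes the letter plus two, matching the
    standard ICD-9 structure.  ``250.01 -> 250``, ``V10.3 -> V10``.
    """
    code = code.strip().upper()
    if not _ICD9_RE.match(code):
        raise ValueError(f"not an ICD-9 code: {code!r}")
    prefix = ""
    if code[0] in "EV":
        prefix, code = code[0], code[1:]
    digits = code.split(".", 1)[0]
    width = 2 if prefix == "V" else 3
    return prefix + digits.zfill(width)[:width]


def to_icd9(
    assocs: list[tuple[str, str]], mapping: dict[str, set[str]]
) -> tuple[DiseaseGeneMap, MappingReport]:
    """Expand source disease ids to 3-digit ICD-9 codes and union-merge.

    One source id may map to several codes (its gene set is assigned to each);
    several source ids collapsing onto one code contribute the union of their
    genes.  Unmapped ids are dropped and recorded in the report.
    """
    report = MappingReport(n_pairs_in=len(assocs))
    out: DiseaseGeneMap = {}
    for disease, gene in assocs:
        codes = mapping.get(disease)
        if not codes:
            report.unmapped_ids.add(disease)
            continue
        report.n_pairs_mapped += 1
        for code in codes:
            out.setdefault(truncate_icd9(code), set()).add(gene)
    if assocs and not out:
        warnings.warn("no disease id could be mapped to ICD-9; result is empty")
    return out, report


def filter_min_genes(m: DiseaseGeneMap, k: int) -> DiseaseGeneMap:
    """Keep diseases annotated with at least ``k`` genes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return {d: set(g) for d, g in m.items() if len(g) >= k}


def remove_pleiotropic(m: DiseaseGeneMap) -> DiseaseGeneMap:
    """Drop every gene associated with more than one disease.

    Diseases whose gene set becomes empty disappear from the result; the
    surviving gene sets are globally disjoint.
    """
    seen: dict[str, int] = {}
    for genes in m.values():
        for g in genes:
            seen[g] = seen.get(g, 0) + 1
    pleiotropic = {g for g, c in seen.items() if c >= 2}
    out = {d: set(g) - pleiotropic for d, g in m.items()}
    out = {d: g for d, g in out.items() if g}
    if m and not out:
        warnings.warn("all genes were pleiotropic; the filtered map is empty")
    return out


def degree_distribution(m: DiseaseGeneMap) -> tuple[dict[int, int], float]:
    """Histogram of disease degrees (|G_i|) plus the mean degree."""
    hist: dict[int, int] = {}
    for genes in m.values():
        hist[len(genes)] = hist.get(len(genes), 0) + 1
    mean = sum(len(g) for g in m.values()) / len(m) if m else float("nan")
    return hist, mean


def combine_maps(maps: list[DiseaseGeneMap], mode: str = "union") -> DiseaseGeneMap:
    """Combine several disease-gene maps over (disease, gene) pairs.

    ``union`` keeps a pair present in any map; ``intersection`` keeps pairs
    present in every map (so a disease survives only with the genes all
    sources agree on).
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps to combine")
    pair_sets = [
        {(d, g) for d, genes in m.items() for g in genes} for m in maps
    ]
    if mode == "union":
        pairs = set().union(*pair_sets)
    elif mode == "intersection":
        pairs = set.intersection(*pair_sets)
    else:
        raise ValueError(f"unknown combine mode: {mode!r}")
    out: DiseaseGeneMap = {}
    for d, g in pairs:
        out.setdefault(d, set()).add(g)
    return out


def write_disease_gene_map(m: DiseaseGeneMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#icd9\tgenes\n")
        for d in sorted(m):
            fh.write(f"{d}\t{','.join(sorted(m[d]))}\n")


def read_disease_gene_map(path) -> DiseaseGeneMap:
    out: DiseaseGeneMap = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            d, genes = line.split("\t")
            out[d] = set(genes.split(","))
    return out
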