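"""Cross-species homolog bookkeeping for DE gene lists.

Maps a mouse gene list through a static mouse→human homology table
(one row per (mouse, human) pair; unmapped mouse genes appear once with a
missing partner), applies the expression-platform availability filter, and
summarizes overlap with a compendium of hypoxia/angiogenesis signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import pandas as pd

from .errors import InputError
from .signatures import GeneSignature

__all__ = [
    "load_homology",
    "save_homology",
    "map_homologs",
    "MappingReport",
    "platform_filter",
    "overlap_summary",
    "OverlapCounts",
]


def load_homology(path) -> pd.DataFrame:
    """Read a homology TSV with columns mouse_gene, human_gene (empty = none)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"mouse_gene", "human_gene"}.issubset(df.columns):
        raise InputError("homology table needs mouse_gene and human_gene columns")
    df = df.copy()
    df.loc[df["human_gene"] == "", "human_gene"] = pd.NA
    return df


def save_homology(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["human_gene"] = out["human_gene"].fillna("")
    out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MappingReport:
    """Distinct human partners of a mouse gene list, plus the partition
    of the input into unmapped / one-to-one / multi-mapped genes."""

    human_genes: Tuple[str, ...]
    n_input: int
    n_unmapped: int
    n_one_to_one: int
    n_multi: int

    @property
    def n_mapped(self) -> int:
        return self.n_one_to_one + self.n_multi

    @property
    def n_human(self) -> int:
        return len(self.human_genes)


def map_homologs(genes: Sequence[str], table: pd.DataFrame) -> MappingReport:
    """Map mouse genes to the distinct union of their human partners.

    Genes absent from the table count as unmapped.  Output order follows
    first appearance of each human gene along the input list.
    """
    mapped = table.dropna(subset=["human_gene"])
    partners = mapped.groupby("mouse_gene")["human_gene"].apply(list).to_dict()
    human: List[str] = []
    seen = set()
    n_unmapped = n_one = n_multi = 0
    for g in dict.fromkeys(genes):
        hs = partners.get(g)
        if not hs:
            n_unmapped += 1
            continue
        distinct = list(dict.fromkeys(hs))
        if len(distinct) == 1:
            n_one += 1
        else:
            n_multi += 1
        for h in distinct:
            if h not in seen:
                seen.add(h)
                human.append(h)
    return MappingReport(
        human_genes=tuple(human),
        n_input=len(dict.fromkeys(genes)),
        n_unmapped=n_unmapped,
        n_one_to_one=n_one,
        n_multi=n_multi,
    )


def platform_filter(genes: Sequence[str], platform: Sequence[str]):
    """Split ``genes`` into (retained, dropped) by platform membership.

    Order-stable: retained genes keep their input order.
    """
    plat = set(platform)
    retained = [g for g in genes if g in plat]
    dropped = [g for g in genes if g not in plat]
    return retained, dropped


@dataclass(frozen=True)
class OverlapCounts:
    """Membership of a gene list against tagged signature collections."""

    n_genes: int
    in_hypoxia: int
    in_angiogenesis: int
    in_both: int

    @property
    def in_neither(self) -> int:
        return self.n_genes - (self.in_hypoxia + self.in_angiogenesis - self.in_both)


def overlap_summary(genes: Sequence[str], compendium: Sequence[GeneSignature]) -> OverlapCounts:
    """Count genes present in hypoxia signatures, angiogenesis signatures,
    both, or neither (by union of each tag's gene sets)."""
    hyp = set()
    ang = set()
    for sig in compendium:
        if sig.tag == "hypoxia":
            hyp.update(sig.genes)
        elif sig.tag == "angiogenesis":
            ang.update(sig.genes)
    gset = list(dict.fromkeys(genes))
    n_h = sum(g in hyp for g in gset)
    n_a = sum(g in ang for g in gset)
    n_b = sum(g in hyp and g in ang for g in gset)
    return OverlapCounts(n_genes=len(gset), in_hypoxia=n_h, in_angiogenesis=n_a, in_both=n_b)
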