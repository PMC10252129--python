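"""Over-representation analysis against GMT gene-set collections.

Significant genes from the meta-analysis are tested for enrichment in each
gene set with the hypergeometric upper tail P(X >= k), BH-adjusted across
all tested terms; reported terms must additionally overlap the gene list in
at least ``min_overlap`` genes (default 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError
from .preprocess import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they are tested against."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def with_universe(self, universe) -> "GeneSetCollection":
        universe = set(universe)
        if not universe:
            raise ValidationError("universe is empty")
        return GeneSetCollection(
            sets=self.sets, descriptions=self.descriptions, universe=universe
        )

    def effective_universe(self) -> set[str]:
        if self.universe is not None:
            return self.universe
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> gene...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate term {name!r}")
            sets[name] = {g for g in genes if g}
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def hypergeom_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def ora(
    significant,
    collection: GeneSetCollection,
    min_overlap: int = 10,
    fdr_max: float = 0.05,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each gene set.

    BH adjustment runs across every tested term (any term with at least one
    member in the universe) before the overlap/FDR report filters, so that
    filtering cannot bias the adjusted p-values. Returns the reported terms
    sorted by FDR ascending (all tested terms when ``keep_all`` is set),
    with columns term, k, K, n, N, p, fdr, genes.
    """
    universe = collection.effective_universe()
    if not universe:
        raise ValidationError("empty universe")
    sig = set(significant)
    outside = len(sig - universe)
    if outside:
        logger.info("ORA: dropping %d significant genes outside the universe", outside)
    sig &= universe
    n = len(sig)
    big_n = len(universe)

    rows = []
    for term, members in collection.sets.items():
        members_u = members & universe
        big_k = len(members_u)
        if big_k == 0:
            continue
        overlap = sig & members_u
        k = len(overlap)
        rows.append(
            {
                "term": term,
                "description": collection.descriptions.get(term, ""),
                "k": k,
                "K": big_k,
                "n": n,
                "N": big_n,
                "p": hypergeom_tail(k, big_n, big_k, n),
                "genes": ",".join(sorted(overlap)),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "description", "k", "K", "n", "N", "p", "fdr", "genes"]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["fdr", "p", "term"], kind="mergesort").reset_index(drop=True)
    out = out[["term", "description", "k", "K", "n", "N", "p", "fdr", "genes"]]
    if keep_all:
        return out
    reported = out[(out["k"] >= min_overlap) & (out["fdr"] < fdr_max)]
    return reported.reset_index(drop=True)
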