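"""Rule-based prediction of bacterial LPS structure from pangenome gene content.

A species' lipid A phenotype is read off its lipopolysaccharide (LPS)
biosynthesis gene complement.  A gene counts as encoded by a species when it
is present in at least half of the genomes of that species' pangenome.  The
classification rules follow the canonical (Raetz) lipid A pathway:

* ``lpxA, lpxB, lpxC, lpxD, lpxK`` — the backbone required to build lipid
  IVA; species encoding all five are Gram-negative LPS producers.
* ``waaA`` (= ``kdtA``) — KDO transferase; adds the KDO2 moiety.
* ``lpxL`` — secondary acyltransferase adding the fifth acyl chain
  (penta-acylation).
* ``lpxM`` / ``lpxJ`` — alternative late acyltransferases adding a sixth
  chain (hexa-acylation).  Hexa-acylated lipid A is the potent human TLR4
  agonist; penta- and tetra-acylated forms are weak agonists or antagonists.

Gene calls may come from two annotation schemata (e.g. InterPro and eggNOG);
evidence is merged by union, except ``lpxM`` where only the first schema is
trusted (the second systematically over-calls it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Full gene vocabulary carried by a pangenome table.
GENE_VOCABULARY: tuple[str, ...] = (
    "lpxA", "lpxB", "lpxC", "lpxD", "lpxH", "lpxK", "waaA",
    "lpxL", "lpxM", "lpxJ",
    "lpxE", "lpxF", "pagL", "pagP",
)

#: Genes required for lipid IVA (the classification backbone). ``lpxH`` is a
#: backbone pathway member but is not part of the operational rule.
CORE_GENES: frozenset[str] = frozenset({"lpxA", "lpxB", "lpxC", "lpxD", "lpxK"})

#: The ten genes the classification rule can consult.
CLASSIFICATION_VOCABULARY: tuple[str, ...] = (
    "lpxA", "lpxB", "lpxC", "lpxD", "lpxH", "lpxK", "waaA", "lpxL", "lpxM", "lpxJ",
)

#: Late acyltransferase modification genes: carried through reporting, never
#: consulted by the acylation rule.
MODIFICATION_GENES: frozenset[str] = frozenset({"lpxE", "lpxF", "pagL", "pagP"})

ACYLATION_LEVELS: tuple[str, ...] = ("none", "tetra", "penta", "hexa")

CATEGORY_NAMES: tuple[str, ...] = (
    "total_lps", "tetra", "penta", "hexa_lpxM", "hexa_lpxJ", "hexa_total",
)

#: Schema channels of a two-channel pangenome table.
SCHEMA_CHANNELS: tuple[str, str] = ("schema_A", "schema_B")


@dataclass(frozen=True)
class LpsStructure:
    """Predicted LPS structural capacity of one species."""

    encodes_lps: bool
    kdo2: bool
    acylation: str
    hexa_routes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.acylation not in ACYLATION_LEVELS:
            raise ValueError(f"unknown acylation level {self.acylation!r}")
        if (self.acylation == "hexa") != bool(self.hexa_routes):
            raise ValueError("hexa_routes must be non-empty iff acylation is hexa")
        if self.acylation != "none" and not self.encodes_lps:
            raise ValueError("acylated structures require encodes_lps")

    @property
    def category(self) -> str:
        """Reporting category: none, tetra, penta, hexa_lpxM or hexa_lpxJ.

        A species encoding both hexa routes is reported under lpxM (it is
        counted in both route tallies but only once in hexa totals).
        """
        if self.acylation != "hexa":
            return self.acylation
        return "hexa_lpxM" if "lpxM" in self.hexa_routes else "hexa_lpxJ"


def merge_annotation_evidence(table: pd.DataFrame) -> pd.DataFrame:
    """Merge a two-channel (schema_A, schema_B) pangenome into one channel.

    Union semantics: the merged genome frequency of a gene is the maximum
    over the two evidence channels — a species identified as encoding a gene
    by at least one schema is taken to encode it.  Exception: ``lpxM`` takes
    only the schema_A value, because the second schema over-identifies it in
    taxa known not to encode it.

    Parameters
    ----------
    table
        Species x (gene, channel) frame with a two-level column index whose
        second level is ``schema_A`` / ``schema_B``.

    Returns
    -------
    Species x gene frame with plain gene columns.
    """
    if not isinstance(table.columns, pd.MultiIndex) or table.columns.nlevels != 2:
        raise ValueError("expected a two-channel table with (gene, schema) columns")
    genes = list(dict.fromkeys(table.columns.get_level_values(0)))
    unknown = sorted(set(genes) - set(GENE_VOCABULARY))
    if unknown:
        raise ValueError(f"unknown gene name(s) in pangenome table: {unknown}")
    merged = {}
    for gene in genes:
        sub = table[gene]
        if gene == "lpxM":
            merged[gene] = sub["schema_A"]
        else:
            merged[gene] = sub.max(axis=1)
    out = pd.DataFrame(merged, index=table.index)
    return out[genes]


def derive_species_gene_set(
    row: pd.Series, presence_threshold: float = 0.5
) -> set[str]:
    """Genes encoded by a species: genome frequency >= threshold (inclusive).

    The default 0.5 corresponds to presence in at least 50% of the
    constituent genomes of the pangenome.
    """
    if not 0.0 < presence_threshold <= 1.0:
        raise ValueError(
            f"presence_threshold must be in (0, 1], got {presence_threshold}"
        )
    return {str(g) for g, f in row.items() if f >= presence_threshold}


def classify_lps_structure(genes: set[str]) -> LpsStructure:
    """Classify a species' LPS capacity from its encoded gene set.

    Rules (total function on any subset of the vocabulary):

    * lipid IVA (``encodes_lps``) iff all of lpxA, lpxB, lpxC, lpxD, lpxK;
    * KDO2-lipid IVA iff additionally waaA;
    * hexa-acylated iff additionally lpxL and (lpxM or lpxJ), recording which
      route(s); penta iff lpxL but neither lpxM nor lpxJ; tetra iff no lpxL.
    """
    encodes = CORE_GENES <= genes
    if not encodes:
        return LpsStructure(False, False, "none")
    kdo2 = "waaA" in genes
    if "lpxL" not in genes:
        return LpsStructure(True, kdo2, "tetra")
    routes = frozenset(g for g in ("lpxM", "lpxJ") if g in genes)
    if routes:
        return LpsStructure(True, kdo2, "hexa", routes)
    return LpsStructure(True, kdo2, "penta")


def classify_pangenome(
    table: pd.DataFrame, presence_threshold: float = 0.5
) -> dict[str, LpsStructure]:
    """Classify every species of a single-channel pangenome table.

    Two-channel tables are merged first.  Returns a species -> structure map.
    """
    if isinstance(table.columns, pd.MultiIndex):
        table = merge_annotation_evidence(table)
    return {
        str(sp): classify_lps_structure(
            derive_species_gene_set(row, presence_threshold)
        )
        for sp, row in table.iterrows()
    }


def structures_frame(structures: dict[str, LpsStructure]) -> pd.DataFrame:
    """Tabular view of structure calls (one row per species)."""
    rows = [
        {
            "species_id": sp,
            "encodes_lps": s.encodes_lps,
            "kdo2": s.kdo2,
            "acylation": s.acylation,
            "routes": "+".join(sorted(s.hexa_routes)),
        }
        for sp, s in structures.items()
    ]
    return pd.DataFrame(
        rows, columns=["species_id", "encodes_lps", "kdo2", "acylation", "routes"]
    ).set_index("species_id")


def tally_lps_categories(structures: dict[str, LpsStructure]) -> dict[str, int]:
    """Count species per predicted category.

    Returns counts for encodes_lps (total Gram-negative LPS-encoding taxa),
    kdo2, each acylation class, and each hexa route.  A species encoding both
    routes counts once in ``hexa`` and once in each route tally.
    """
    tally = {
        "total_lps": 0, "kdo2": 0,
        "tetra": 0, "penta": 0, "hexa": 0,
        "hexa_lpxM": 0, "hexa_lpxJ": 0,
        "none": 0,
    }
    for s in structures.values():
        if not s.encodes_lps:
            tally["none"] += 1
            continue
        tally["total_lps"] += 1
        if s.kdo2:
            tally["kdo2"] += 1
        tally[s.acylation] += 1
        for route in s.hexa_routes:
            tally[f"hexa_{route}"] += 1
    assert tally["tetra"] + tally["penta"] + tally["hexa"] == tally["total_lps"]
    return tally


def category_abundance(
    taxa: pd.DataFrame, structures: dict[str, LpsStructure]
) -> pd.DataFrame:
    """Per-sample relative abundance of each LPS category.

    Parameters
    ----------
    taxa
        Samples x taxa read-count frame (fraction of classified reads is
        computed per row).
    structures
        Taxon -> :class:`LpsStructure`.  Taxa without a call are treated as
        non-LPS (conservative: mirrors taxa absent from the catalogue) and a
        warning lists them.

    Returns
    -------
    Samples x {total_lps, tetra, penta, hexa_lpxM, hexa_lpxJ, hexa_total}
    frame of fractions of classified reads.  Per sample,
    ``tetra + penta + hexa_total == total_lps``.
    """
    totals = taxa.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero classified reads: {list(zero.index)}"
        )
    missing = [t for t in taxa.columns if t not in structures]
    if missing:
        warnings.warn(
            f"{len(missing)} taxa without a structure call treated as non-LPS: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )
    frac = taxa.div(totals, axis=0)
    out = pd.DataFrame(0.0, index=taxa.index, columns=list(CATEGORY_NAMES))
    for taxon in taxa.columns:
        s = structures.get(str(taxon))
        if s is None or not s.encodes_lps:
            continue
        col = frac[taxon]
        out["total_lps"] += col
        if s.acylation == "hexa":
            out["hexa_total"] += col
            for route in s.hexa_routes:
                out[f"hexa_{route}"] += col
        else:
            out[s.acylation] += col
    resid = (
        out["tetra"] + out["penta"] + out["hexa_total"] - out["total_lps"]
    ).abs().max()
    assert resid < 1e-9, "category partition identity violated"
    return out
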