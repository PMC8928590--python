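"""Gene/QTL annotation of region sets and Fisher/BH term enrichment.

Regions are intersected (>= 1 bp) with a gene annotation (GFF3 or GTF,
read through ``gffutils``), recording which genes and which feature kinds
(transcript, exon, CDS, UTRs, start/stop codon) each region touches.

Term enrichment is deliberately generic: given a target subset of a
universe of items (genes, regions ...) and a term -> items map (GO terms,
KEGG pathways, QTL traits ...), each term is tested with a two-sided
Fisher exact test on the 2x2 table (in/out of target x with/without term)
and corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import Region

__all__ = [
    "annotate_features",
    "fisher_enrichment",
    "read_term_map",
    "qtl_term_map",
    "read_qtl_bed",
]

FEATURE_KINDS = (
    "transcript",
    "mRNA",
    "exon",
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "five_prime_utr",
    "three_prime_utr",
    "start_codon",
    "stop_codon",
)


def _gene_id(db, feature) -> str | None:
    for key in ("gene_id", "geneID", "gene"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    try:
        for parent in db.parents(feature, featuretype="gene"):
            return parent.id
    except Exception:
        pass
    return None


def annotate_features(
    regions: Sequence[Region], annotation_path: str | Path
) -> pd.DataFrame:
    """Overlap regions with gene features from a GFF3/GTF file.

    Returns a long-form table (region_id, chrom, start, end, gene_id,
    feature_type) with one row per overlapped feature; regions hitting
    nothing are absent.  Intersection is >= 1 bp.
    """
    import gffutils

    annotation_path = Path(annotation_path)
    if not annotation_path.exists():
        raise FileNotFoundError(f"annotation file not found: {annotation_path}")
    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for i, r in enumerate(regions):
        # gffutils uses 1-based inclusive GFF coordinates
        try:
            hits = list(db.region(seqid=r.chrom, start=r.start + 1, end=r.end))
        except ValueError:
            continue  # chromosome absent from the annotation
        for f in hits:
            if f.featuretype not in FEATURE_KINDS:
                continue
            rows.append(
                {
                    "region_id": i,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "gene_id": _gene_id(db, f) or f.id,
                    "feature_type": f.featuretype,
                }
            )
    return pd.DataFrame(
        rows, columns=["region_id", "chrom", "start", "end", "gene_id", "feature_type"]
    )


def fisher_enrichment(
    target: Iterable[Hashable],
    universe: Iterable[Hashable],
    term_map: Mapping[str, Iterable[Hashable]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher exact + BH-adjusted enrichment of each term in ``target``.

    ``target`` must be a subset of ``universe``; terms are restricted to
    universe members before testing.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    target_set = set(target)
    stray = target_set - universe_set
    if stray:
        raise ValueError(f"target items outside the universe: {sorted(stray)[:5]} ...")
    n_target = len(target_set)
    n_bg = len(universe_set) - n_target

    rows = []
    for term, items in term_map.items():
        with_term = set(items) & universe_set
        a = len(with_term & target_set)          # target, with term
        b = n_target - a                         # target, without term
        c = len(with_term) - a                   # background, with term
        d = n_bg - c                             # background, without term
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "term": term,
                "hits_target": a,
                "hits_universe": len(with_term),
                "n_target": n_target,
                "n_universe": len(universe_set),
                "odds_ratio": odds,
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "hits_target", "hits_universe", "n_target",
                 "n_universe", "odds_ratio", "p_value"],
    )
    if len(df):
        _, padj, _, _ = multipletests(df["p_value"], method="fdr_bh")
        df["p_adjusted"] = padj
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["p_adjusted"] = []
        df["significant"] = []
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


# -- Term-map and QTL helpers -------------------------------------------------


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a term<TAB>item two-column table into a term -> items map."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term, item = line.split("\t")[:2]
            out.setdefault(term, set()).add(item)
    return out


def read_qtl_bed(path: str | Path) -> list[Region]:
    """BED with a 4th trait column -> regions with payload {'trait': ...}."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            trait = parts[3] if len(parts) > 3 else "unknown"
            out.append(Region(parts[0], int(parts[1]), int(parts[2]), {"trait": trait}))
    return out


def qtl_term_map(
    regions: Sequence[Region], qtls: Sequence[Region]
) -> dict[str, set[int]]:
    """Map each QTL trait to the indices of target regions it intersects."""
    out: dict[str, set[int]] = {}
    for q in qtls:
        trait = str((q.payload or {}).get("trait", "unknown"))
        for i, r in enumerate(regions):
            if r.chrom == q.chrom and min(r.end, q.end) > max(r.start, q.start):
                out.setdefault(trait, set()).add(i)
    return out
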