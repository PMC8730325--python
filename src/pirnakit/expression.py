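"""Gene and transposon-family expression quantification (RPKM) and
fold-change tables.

Transposons are quantified per family with copies pooled (family length =
summed copy lengths).  Differential-expression modelling is deliberately
not included; the count matrix is exported in a layout any DE tool accepts.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .align import AlignmentSet
from .annotation import FeatureIndex, FeatureSet


def quantify(aln: AlignmentSet, features: FeatureSet,
             index: Optional[FeatureIndex] = None,
             overlap_frac: float = 0.5) -> pd.DataFrame:
    """Apportioned counts and RPKM per gene and per transposon family.

    A placement is assigned to a feature when at least ``overlap_frac`` of
    the read overlaps it; transposons take precedence over genes, and each
    placement is assigned at most once so total mapped weight is conserved
    across features plus the ``unannotated`` row.
    """
    if index is None:
        index = features.build_index()
    mapped = aln.mapped_weight()
    if mapped <= 0:
        raise ValueError("no mapped reads to quantify")
    lengths: dict[str, float] = {}
    kinds: dict[str, str] = {}
    for f in features:
        if f.klass == "gene" and f.feature_id:
            lengths[f.feature_id] = f.length
            kinds[f.feature_id] = "gene"
        elif f.klass == "transposon" and f.family:
            lengths[f.family] = lengths.get(f.family, 0) + f.length
            kinds[f.family] = "transposon_family"
    counts = {k: 0.0 for k in lengths}
    unannotated = 0.0
    for _read, p, w in aln.iter_weighted():
        need = overlap_frac * (p.end - p.start)
        target = None
        for f in index.overlapping(p.contig, p.start, p.end):
            if min(p.end, f.end) - max(p.start, f.start) < need:
                continue
            if f.klass == "transposon" and f.family:
                target = f.family
                break
            if f.klass == "gene" and f.feature_id and target is None:
                target = f.feature_id
        if target is None:
            unannotated += w
        else:
            counts[target] += w
    lib_millions = mapped / 1e6
    rows = [{"feature": k, "kind": kinds[k], "length": lengths[k],
             "count": counts[k],
             "rpkm": counts[k] / (lengths[k] / 1000.0 * lib_millions)}
            for k in sorted(lengths)]
    rows.append({"feature": "unannotated", "kind": "unannotated",
                 "length": np.nan, "count": unannotated, "rpkm": np.nan})
    df = pd.DataFrame(rows).set_index("feature")
    df.attrs["mapped_weight"] = mapped
    return df


def fold_change(table_a: pd.DataFrame, table_b: pd.DataFrame,
                pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-feature log2 fold change of B over A after library-size scaling.

    Counts are scaled to per-million of each library's mapped weight before
    the pseudocount is added, so equal relative abundance gives 0.  Rows
    with absolute fold change > 2 (|log2fc| > 1) are flagged.
    """
    common = table_a.index.intersection(table_b.index)
    common = common[common != "unannotated"]
    if len(common) != len(table_a.index.drop("unannotated", errors="ignore")):
        raise ValueError("feature rows of the two tables do not match")
    ma = table_a.attrs.get("mapped_weight", table_a["count"].sum())
    mb = table_b.attrs.get("mapped_weight", table_b["count"].sum())
    cpm_a = table_a.loc[common, "count"] / ma * 1e6
    cpm_b = table_b.loc[common, "count"] / mb * 1e6
    log2fc = np.log2((cpm_b + pseudocount) / (cpm_a + pseudocount))
    return pd.DataFrame({
        "count_a": table_a.loc[common, "count"],
        "count_b": table_b.loc[common, "count"],
        "log2_fold_change": log2fc,
        "fc_gt2": np.abs(log2fc) > 1.0,
    })
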