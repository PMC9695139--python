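"""Tabular summaries of pipeline results.

Everything here is a plain :class:`pandas.DataFrame` factory so results can
be written as TSV, inspected interactively, or plotted by the caller; no
figure is produced implicitly.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .methylation import MethylationTable
from .rna import BINS, ReadClassification, StrictContig
from .smallrna import SmallRnaProfile


def spectrum_table(spectrum: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"bin": list(BINS), "fraction": [spectrum[b] for b in BINS]}
    )


def classification_table(classifications: Sequence[ReadClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "best_ref_id": c.best_ref_id,
                "strand": c.strand,
                "mismatches": c.mismatches,
                "aligned_len": c.aligned_len,
                "mismatch_pct": round(c.mismatch_pct, 4),
                "bin": c.bin,
                "region": c.region or "",
            }
            for c in classifications
        ]
    )


def contig_table(contigs: Sequence[StrictContig], genome_rows: Sequence[dict]) -> pd.DataFrame:
    by_id = {r["contig_id"]: r for r in genome_rows}
    return pd.DataFrame(
        [
            {
                "contig_id": c.id,
                "length": len(c.seq),
                "n_reads": len(c.members),
                "max_extension": max(c.extension_log, default=0),
                "best_ref_id": by_id.get(c.id, {}).get("best_ref_id", ""),
                "best_identity": by_id.get(c.id, {}).get("best_identity", float("nan")),
                "identical": by_id.get(c.id, {}).get("identical", False),
            }
            for c in contigs
        ]
    )


def smallrna_tables(profile: SmallRnaProfile) -> tuple[pd.DataFrame, pd.DataFrame]:
    lengths = pd.DataFrame(
        sorted(profile.length_hist.items()), columns=["length_nt", "count"]
    )
    regions = pd.DataFrame(
        [
            {"region": k, "count": v, "fraction": v / profile.n_total if profile.n_total else 0.0}
            for k, v in profile.region_hist.items()
        ]
    )
    return lengths, regions


def methylation_matrix(table: MethylationTable) -> pd.DataFrame:
    """Clone x site call matrix mirroring a lollipop plot: one row per clone."""
    cols = [f"C{pos}_{ctx}" for pos, ctx in table.sites]
    rows = {
        cid: {col: call for col, call in zip(cols, calls)}
        for cid, calls in table.calls.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def methylation_summary(table: MethylationTable) -> pd.DataFrame:
    rows = [{"context": "all", "pct_methylated": table.pct_methylated}]
    for ctx, pct in table.pct_by_context().items():
        rows.append({"context": ctx, "pct_methylated": pct})
    return pd.DataFrame(rows)
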