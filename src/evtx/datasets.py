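"""Published per-sample accounting from a five-donor plasma-EV sequencing run.

These small tables ship with the package as worked inputs for the
run-summary arithmetic: per-sample raw/post-filter/pool read counts (with
the rRNA percentage as reported, since the underlying rRNA read count is
not published) and per-sample distinct-transcript counts per RNA category
at the >=2-read threshold.  All derived columns — percentages and the
Average row — are recomputed by :func:`evtx.quantify.summarize_run`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .quantify import SampleStats

__all__ = ["plasma_ev_run_counts", "plasma_ev_run_stats", "plasma_ev_transcript_counts"]


def _load(name: str) -> pd.DataFrame:
    path = resources.files("evtx").joinpath(f"data/{name}")
    with path.open() as handle:
        df = pd.read_csv(handle, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


def plasma_ev_run_counts() -> pd.DataFrame:
    """Raw per-sample read-accounting counts (five plasma donors)."""
    return _load("plasma_ev_run_summary.tsv")


def plasma_ev_run_stats() -> list[SampleStats]:
    """The same accounting as :class:`~evtx.quantify.SampleStats` records."""
    return [
        SampleStats(
            sample_id=row.sample,
            raw_reads=int(row.raw_reads),
            post_filter_reads=int(row.post_filter_reads),
            short_pool=int(row.short_pool),
            mirbase_mapped=int(row.mirbase_mapped),
            ensembl_mapped=int(row.ensembl_mapped),
            pct_rrna_given=float(row.pct_rrna),
        )
        for row in plasma_ev_run_counts().itertuples(index=False)
    ]


def plasma_ev_transcript_counts() -> pd.DataFrame:
    """Distinct transcripts per RNA category per sample (>=2-read rule)."""
    return _load("plasma_ev_transcript_counts.tsv")
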