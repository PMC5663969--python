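"""Recompute the five-donor run-summary table from its per-sample counts.

The package ships the published per-sample accounting of a five-donor
plasma-EV sequencing run.  All derived columns are recomputed here: removal
percentages relative to raw reads, pool percentages relative to post-filter
reads, the reads-other identity (post-filter minus miRBase-mapped), and the
Average row (means of counts; means of per-sample percentages).
"""

from evtx.datasets import plasma_ev_run_stats, plasma_ev_transcript_counts
from evtx.quantify import round_half_up, summarize_run

table = summarize_run(plasma_ev_run_stats())
print(table.to_string(index=False))
print()

avg = table[table["sample"] == "Average"].iloc[0]
print(f"average raw reads/sample: {avg['raw_reads']:,} "
      f"({avg['pct_removed_by_filter']}% removed by screening, "
      f"{avg['pct_rrna']}% rRNA)")
print(f"average short pool: {avg['short_pool']:,} reads "
      f"({avg['pct_short_pool']}% of post-filter)")

counts = plasma_ev_transcript_counts()
print()
print("average distinct transcripts per category (>= 2 reads):")
for col in counts.columns[1:]:
    print(f"  {col:>16}: {int(round_half_up(counts[col].mean(), 0))}")
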