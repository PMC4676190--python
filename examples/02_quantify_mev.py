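"""Count reads per called transcript and summarize expression as MEVs.

The mean expression value (MEV) of a transcript is its read count divided
by its length (reads/nt); the cumulative MEV uses all libraries, the
condition-specific MEVs one condition's libraries.  A transcript counts
as detected when its cumulative MEV reaches 1 read/nt.
"""

from srna_atlas import coverage, discovery, quantify, synthetic

truth, counts, tracks, reads = synthetic.default_experiment(seed=1)
pooled = coverage.pool(list(tracks.values()))
calls = discovery.call_transcripts(pooled, truth.gene_likes()).calls

cm = quantify.count_reads(reads, calls, counts.samples)
mevs = quantify.mev_table(cm)
print("first three transcripts:")
print(mevs.head(3).round(1))

print("\ncumulative MEV histogram (reads/nt):")
print(quantify.mev_bins(mevs["cumulative"]).to_string())

print("\ntranscript length histogram (nt, 25-nt bins):")
bins = quantify.length_bins([c.length for c in calls])
print(bins[bins > 0].to_string())

detected = discovery.detection_status(cm, threshold=1.0)
print(f"\ndetected (cumulative MEV >= 1): {int(detected.sum())}/{len(detected)}")
print("A transcript below that floor would be reported as transcribed but "
      "undetected rather than dropped.")
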