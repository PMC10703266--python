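# data/

Drop-in location for externally published measurements.

`human_subject_slopes.csv` (or `.xlsx`) — per-participant psychometric
slopes from the human probe-timing experiments, one row per participant
with columns for the participant id, the condition, the slope under the
absolute (duration-based) deviation coding and the slope under the
relative (rhythm-based) coding. `tempopred.pipeline.ingest_supplementary`
reads either format with flexible column naming; the acceptance test for
the human dominance-curve fit fails until this file is provided.
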