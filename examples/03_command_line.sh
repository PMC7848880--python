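#!/bin/sh
# The same workflow from the shell: simulate an experiment to disk, run the
# batch pipeline on it, and inspect the outputs.
set -e

gcscore simulate --n-probesets 1000 --de-fraction 0.02 --seed 7 -o /tmp/gcs_demo
gcscore batch /tmp/gcs_demo/chip /tmp/gcs_demo/design.csv \
    --fdr-cut 0.05 --seed 7 -o /tmp/gcs_demo/out

echo "--- selected probesets (results.csv, selected==1) ---"
head -1 /tmp/gcs_demo/out/results.csv
awk -F, '$6 == 1' /tmp/gcs_demo/out/results.csv | head

echo "--- ground truth ---"
head /tmp/gcs_demo/truth.csv
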