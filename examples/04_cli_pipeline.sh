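#!/usr/bin/env bash
# The same pipeline from the shell: simulate a study, extract ROM angles,
# and produce the reliability + regression reports.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

cat > "$workdir/design.yaml" <<'YAML'
scenario:
  movement: Hip Flexion and Extension
  side: left
  duration: 6.0
study:
  n_subjects: 6
  n_trials: 3
  population_mean_rom: 100.0
  between_subject_sd: 9.0
  within_subject_sd: 2.0
  seed: 3
noise:
  landmark_sigma: 0.003
  seed: 3
YAML

rom simulate --design "$workdir/design.yaml" --out "$workdir/study"
rom compute  --manifest "$workdir/study/manifest.csv" --out "$workdir/rom.csv"
rom report   --rom "$workdir/rom.csv" --out "$workdir/reliability.csv" \
             --regression-out "$workdir/regression.csv"

echo "--- rom.csv (head) ---"
head -4 "$workdir/rom.csv"
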