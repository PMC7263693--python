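# Demo configuration for `meiomap run -c examples/pipeline_config.yaml -o out/`
# Simulates a 3-chromosome intercross, runs QC -> grouping -> ordering ->
# centromere mapping -> QTL scan -> recombination rates, and writes one TSV
# (+ provenance JSON) per stage.
seed: 11
genome:
  chromosomes:
    - {name: chr0, female_length: 80.0, male_length: 80.0, physical_length: 40000000,
       centromere_pos: 40.0, male_telomere_fraction: 0.1}
    - {name: chr1, female_length: 80.0, male_length: 80.0, physical_length: 40000000,
       centromere_pos: 0.0, male_telomere_fraction: 0.1}
    - {name: chr2, female_length: 80.0, male_length: 80.0, physical_length: 40000000,
       centromere_pos: 0.0, male_telomere_fraction: 0.1}
  markers_per_chromosome: 80
families:
  diploid:
    - {id: F1, n_offspring: 100}
  gynogenetic: {n_offspring: 40}
trait:
  qtl:
    - {chromosome: chr0, position: 40.0, additive: 1.2}
  residual_sd: 1.0
  type: normal
thresholds:
  n_perm: 100      # demo scale; use 1000 for reported p-values
  rate_reps: 20
  rate_pairs: 50
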