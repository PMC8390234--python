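# nucstates

Nucleosome-level chromatin state modeling. `nucstates` learns discrete
hidden Markov model states over *positioned nucleosomes* — each nucleosome
is one observation whose symbol encodes the combination of histone-mark
peaks covering it — then characterizes every state by its nucleosome
organization (array structure, phasing, spacing, positioning) and scores
gene-body states for skipped-exon splicing potentiality.

## What it does

1. **Observation encoding** (`nucstates.obs_encoding`) — nucleosome calls,
   histone-mark peaks (narrowPeak/broadPeak/BED) and a gene annotation are
   combined into directional per-gene integer sequences over the `2**n`
   mark-subset alphabet (e.g. 128 symbols for 7 marks; a nucleosome with
   H3K4me3 + H3K79me2 gets symbol 9 = 0b0001001).
2. **HMM training** (`nucstates.hmm_core`) — two rounds of Baum-Welch:
   a grid of state counts with seeded restarts is trained and the
   lowest-BIC model selected; states holding < 0.5% of Viterbi-assigned
   nucleosomes are removed with their outgoing transition mass evenly
   redistributed, then the pruned model is retrained. Viterbi decoding
   assigns a state to every nucleosome; emission rows are marginalized by
   mark bit into a mark–state matrix.
3. **Nucleosome organization** (`nucstates.nuc_org`) — same-state runs with
   dyad gaps < 350 bp form arrays. Per-state array coverage (10 bp/point)
   is averaged over 1 kb, linearly interpolated to 1 bp/point, and scored:
   phasing = 1000 × the peak Welch spectral density in the 4–10 Hz band
   (periods 100–250 bp), spacing = mean distance between local maxima, and
   positioning = interquartile-normalized combination of caller attributes
   (height, width, area, peak/valley p-values), validated against a
   raw-read reference score.
4. **Annotation** (`nucstates.annotation`) — per-state frequency profiles
   over Distal / Proximal / Promoter / Gene-body / Downstream regions,
   dominant-region calls, mark calls, and the functional-state summary
   table.
5. **Splicing** (`nucstates.splicing`) — skipped-exon events are split into
   reliable/unreliable groups (X+Y ≥ N with Y ≥ 1; CI-width vs. median);
   per state, the splicing potentiality is the product of the normalized
   discrete Fréchet distance between group signals, the normalized
   positioning difference, and the normalized event-count coefficient; an
   SE affinity compares observed event counts against a random-association
   null.
6. **Synthetic data** (`nucstates.synthetic`) — seeded generators for every
   input format (genomes, ground-truth HMMs with emitted mark peaks,
   periodic array signals, well/fuzzy read pileups, SE tables), used by the
   test suite so nothing needs downloading.

## CLI

```bash
# generate a synthetic input set with known ground truth
nucstates simulate --out-dir sim --seed 7 --n-genes 30 --n-states 4 --n-marks 3

# individual stages
nucstates init   --nucs sim/nucleosomes.tsv --genes sim/genes.refgene.tsv \
                 --peaks H3K4me3=sim/H3K4me3.narrowPeak ... --out obs.tsv
nucstates train  --obs obs.tsv --out model.json
nucstates decode --obs obs.tsv --model model.json --nucs sim/nucleosomes.tsv --out states.bed
nucstates organize --states states.bed --nucs sim/nucleosomes.tsv --out organization.tsv
nucstates annotate --model model.json --org organization.tsv --states states.bed \
                   --nucs sim/nucleosomes.tsv --genes sim/genes.refgene.tsv --out summary.tsv
nucstates splice --se sim/se_events.tsv --states states.bed \
                 --nucs sim/nucleosomes.tsv --out spse.tsv

# or chain everything
nucstates run-all --nucs ... --genes ... --peaks MARK=path ... --se ... --out-dir out
```

All stages accept `--config config.yaml` (see `nucstates.config.RunConfig`
for every knob: mark ordering, overlap fraction, state range/replicates,
iteration caps, pruning cutoff, Welch frame/hop, quantile cutoffs, SE rule
parameters, seed). Outputs are plain TSV/BED/JSON stamped with the config
hash; identical config + seed reproduces outputs bit for bit.

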