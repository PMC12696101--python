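# mfxduet

Post-processing for **two-colour MINFLUX** single-molecule localisation
microscopy. Given a table of localisation events — trace id, position
(nm), emission frequency (efo, kHz), and per-iteration detection-channel
readings — `mfxduet` separates two spectrally overlapping dyes, reduces
blinking traces to molecular positions, clusters them per colour, and
measures cross-colour nearest-neighbour cluster distances. It is aimed at
microscopists quantifying the separation of two labelled molecular
species at nanometre scale, e.g. a receptor and an ER tether protein
across a membrane contact site.

## Method

For each event the detection channel ratio (DCR) readings of its
iterations are pooled photon-weighted,

    pooled_dcr = Σᵢ dcrᵢ · echᵢ / Σᵢ echᵢ ,

and a two-component Gaussian mixture π₁𝒩(μ₁, σ₁²) + π₂𝒩(μ₂, σ₂²) is
fitted to the pooled values by EM. An event is assigned colour A or B when
its posterior for that component exceeds 0.95, else `not_defined`; each
trace takes the modal event colour (ties and `not_defined` modes are
excluded). Localisations are then filtered by efo < 80 kHz and traces by
> 3 surviving localisations; trace centroids are clustered per colour with
DBSCAN (eps = 150 nm, min_pts = 10); and for every cluster of one colour
the distance to the nearest opposite-colour cluster centre is found with a
K-D tree and histogrammed. A synthetic-data module generates localisation
tables with known dye ratios, blinking statistics and inter-colour cluster
pairs at a configurable true separation, with full ground truth, so the
whole chain is testable without raw acquisitions.

## Worked example

Simulate 50 inter-colour cluster pairs at a true 28 nm separation and run
the full pipeline:

```python
from mfxduet import SimulationConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, simulation=SimulationConfig(seed=1, n_pairs=50))
res = run_pipeline(cfg, "demo_run")
print("model means:", [round(m, 4) for m in res.model.means])
print("filters:", res.report["filters"])
print("nn:", res.report["nn"]["headline"])
```

prints

```
model means: [0.2981, 0.6453]
filters: {'n_input_events': 11306, 'n_unmixing_excluded': 28, 'n_efo_dropped': 1401,
          'n_short_trace_dropped': 614, 'n_kept': 9263, 'n_traces_out': 1367}
nn: {'direction': 'b2a', 'n': 40, 'mean_nm': 219.7475855787997,
     'median_nm': 28.474539975059294, 'modal_bin_left_nm': 25.0, 'bin_width_nm': 5.0}
```

The mixture recovered the two dye DCR centres (true values 0.30/0.65);
of 11,306 events, 28 belonged to traces excluded by the colour vote,
1,401 fell to the efo filter and 614 to the trace-length filter; the B→A
median nearest-neighbour distance of **28.5 nm** recovers the simulated
28 nm pair separation (the mean is larger because clusters that lost
their partner to filtering pair with a distant stranger; the median and
the 25–30 nm modal bin are the robust estimates). `demo_run/` holds the
intermediates (`assigned.csv`, `centroids.csv`, `clusters.csv`,
`nn.csv`, `nn_hist.csv`) and `report.json` with all stage counts.

The same chain is available from the shell:

```sh
mfxduet simulate --config sim.yaml --out events.csv --truth truth.csv
mfxduet unmix --in events.csv --out assigned.csv
mfxduet filter --in assigned.csv --out centroids.csv --report counts.json
mfxduet cluster --in centroids.csv --out clusters.csv
mfxduet nn --in clusters.csv --out nn.csv --hist nn_hist.csv
# or everything at once:
mfxduet run --config run.yaml --out-dir out/
```

`mfxduet simulate --show-defaults` prints every generator default;
`mfxduet recover` sweeps true separations × seeds and reports estimated
medians against ground truth.

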