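# evconv

An event-driven convolutional network simulator for AER (address-event
representation) spike streams, modelled on a configurable FPGA
convolutional node:

* **`evconv.aer_io`** — read/write/validate AER event streams (CSV and a
  plain 8-byte binary AEDAT dialect), integer tick timestamps, playback
  slow-down.
* **`evconv.conv_unit`** — the convolutional unit: an integrate-and-fire
  pixel array with multi-kernel event convolution, global leakage toward
  the reset value, saturating fixed-point state registers, a cycle-level
  cost model (router-in + init + 16 cycles/weight + router-out), and a
  hardware-faithful **rate-saturation (refractory) mechanism** that
  stores only an 8-bit slice of the 32-bit allow time per pixel, with an
  overflow flag, a pending-delta flag and a periodic refresh pulse.  The
  delta-t correction makes the saturated output rate exactly `1/T_R`.
* **`evconv.router`** — destination-driven routing on a 2D mesh:
  dimension-order (column-first) shortest paths, local delivery, and
  cloning to multiple destinations with per-destination kernel ids.
* **`evconv.network`** — network assembly (grids of conv nodes and
  router-only slots, splitter/merger, subsample-by-bit-shift links), a
  logical-time discrete-event engine with FIFO occupancy and the
  input-drop traffic-control rule, architecture counters, YAML configs,
  and the bundled 22-node / 4-layer poker-symbol topology
  (5,116 neurons, 531,232 synapses, 94 kernels).
* **`evconv.param_map`** — two-stage frame-to-event parameter mapping:
  deterministic threshold/kernel/leak-rate scaling to the fixed-point
  ranges, plus a seeded simulated-annealing fine-tuner.
* **`evconv.stimulus`** — synthetic inputs: ISI-normal single-address
  spike trains and DVS-like ON/OFF streams from symbol masks moving
  across a 32×32 field.
* **`evconv.analysis`** — saturation curves (f_out vs f_in per T_R),
  the strict-maximum symbol decision rule, stream statistics
  (eps/Keps/Meps) and energy-per-classification arithmetic.

## CLI

One entry point, `evconv`:

```sh
evconv count-arch --poker                      # 5116 neurons, 531232 synapses, 94 kernels
evconv gen-config --poker --out poker.yaml     # dump the bundled topology
evconv gen-stimulus --kind symbol --symbol club --out stim.csv
evconv simulate --poker --input stim.csv --slowdown 10 --seed 1 --out log.json
evconv characterize-refractory --tr 0.0512 --th 10 --fin-grid 100,1000,2000 --out curve.csv
evconv map-params --params params.tsv --out scaled.tsv
evconv classify --events out.csv --intervals iv.csv --out result.json
```

Every JSON artifact embeds a run manifest (seed, config, slow-down,
tick duration, version); reruns are byte-identical.

## Notes

* Timestamps are integer clock ticks; the default tick is 20 ns
  (50 MHz clock).  The tick duration is carried on every stream.
* The bundled poker topology ships with representative kernels (Gabor
  patches in the first layer, seeded integers elsewhere); the originally
  trained weights were never published, so recognition accuracy on real
  recordings is out of scope — topology, counts, timing and traffic
  behaviour are fully exercised.
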