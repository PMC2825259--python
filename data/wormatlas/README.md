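# Revised somatic wiring dataset (not bundled)

The reference-value tests in `tests/test_acceptance.py` and any real-data
run of the pipeline expect the revised wiring tables of the *C. elegans*
somatic nervous system (the "Neuronal connectivity II" dataset distributed
via WormAtlas, `www.wormatlas.org/neuronalwiring.html#NeuronalconnectivityII`).
The data are not redistributed here; download them and convert to the two
files below (tab-separated, one header row):

- `connections.tsv` — columns `Neuron1, Neuron2, Type, Nbr`, where `Type`
  is one of `S, Sp, R, Rp, EJ, NMJ` and `Nbr` is the multiplicity. This is
  the "connectivity" sheet exported as TSV, unchanged.
- `neurons.tsv` — columns `Neuron, Position, Ganglion, NType` and
  optionally `Lineage`: one row per somatic neuron with its cell-body
  position along the longitudinal axis (fraction of body length), its
  ganglion label (G1-G10, with G10 the ventral cord) and its type
  (sensory/motor/interneuron/polymodal).

Without these files the real-data tests fail with a message pointing here;
all synthetic-data tests are unaffected.
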