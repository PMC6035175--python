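# Full-complex analysis config for the Kif2A-NM : (alpha/beta-tubulin)2 :
# DARPin crystal structure, with comparator entries for motif and helix
# displacement and the SEC-SAXS profile for solution validation.
#
# Fetch inputs first:  python scripts/fetch_reference_data.py
#
# NOTE chain-role mapping: the deposited entry does not label which chain
# is alpha1/beta1/alpha2/beta2/kinesin/darpin.  Inspect the file (chain
# lengths and sequences distinguish kinesin ~560 aa constructs, tubulin
# ~440 aa, DARPin ~160 aa; alpha vs beta tubulin separate by sequence)
# and adjust the ids below before running.

structure_path: reference_data/6bbn.cif

chain_roles:
  kinesin: "K"   # verify against the file
  alpha1: "A"
  beta1: "B"
  alpha2: "C"
  beta2: "D"
  darpin: "E"

motifs:
  # core selections exclude the disordered tubulin C-terminal tails
  alpha1_core: {ranges: [[1, 437]], atoms: [CA]}
  beta1_core: {ranges: [[1, 426]], atoms: [CA]}
  alpha2_core: {ranges: [[1, 437]], atoms: [CA]}
  beta2_core: {ranges: [[1, 426]], atoms: [CA]}

interface_groups:
  neck_vs_alpha1beta1:
    kind: buried_area
    group_a: [{chain: "K", ranges: [[157, 195]]}]
    group_b: [{chain: "A"}, {chain: "B"}]
  kvd_vs_alpha2:
    kind: contacts
    group_a: [{chain: "K", ranges: [[262, 264]]}]
    group_b: [{chain: "C"}]
    cutoff: 4.0

comparators:
  # T7-H8 motif of alpha2-tubulin vs the Kif2C-tubulin complex; the frame
  # is the alpha2 chain with the motif itself excluded
  - name: t7h8_vs_kif2c_complex
    path: reference_data/5mio.cif
    frame_a: {chain: "C", ranges: [[1, 243], [261, 437]]}
    frame_b: {chain: "B", ranges: [[1, 243], [261, 437]]}   # verify chain
    motif_a: {chain: "C", ranges: [[244, 260]]}
    motif_b: {chain: "B", ranges: [[244, 260]]}
  - name: t7h8_vs_stathmin_complex
    path: reference_data/4eb6.cif
    frame_a: {chain: "C", ranges: [[1, 243], [261, 437]]}
    frame_b: {chain: "C", ranges: [[1, 243], [261, 437]]}   # verify chain
    motif_a: {chain: "C", ranges: [[244, 260]]}
    motif_b: {chain: "C", ranges: [[244, 260]]}

helix_comparison:
  # alpha4/alpha5 rotation of the motor domain vs isolated ADP-Kif2A,
  # frames superposed on the P-loop (Walker motif GQTGSGKT region)
  name: alpha4_alpha5_vs_apo
  path: reference_data/2gry.cif
  frame_a: {chain: "K", ranges: [[295, 305]]}
  frame_b: {chain: "A", ranges: [[295, 305]]}
  helices_a: {chain: "K", ranges: [[465, 500], [508, 525]]}
  helices_b: {chain: "A", ranges: [[465, 500], [508, 525]]}

saxs:
  experimental_profile: reference_data/sasdcr9.dat
  qmax: 0.25
  mode: auto          # residue-level coarse graining above 10k atoms
  qrg_limit: 1.3

superpose:
  max_cycles: 5
  reject_factor: 2.0

sasa:
  probe_radius: 1.4
  n_points: 960

output_dir: results
seed: 1
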