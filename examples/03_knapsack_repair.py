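"""Mass-constrained sequence repair with the exact knapsack solver.

Given per-position token probabilities and a precursor-mass window, the solver
picks one residue per position maximizing total log-probability subject to the
total residue mass landing inside the window — the post-processing stage that
turns a nearly-right peptide into a mass-consistent one.
"""

import numpy as np

from pepflow import AminoAcidVocabulary, Peptide, mass_window, peptide_mass
from pepflow.constants import WATER_MASS
from pepflow.knapsack import knapsack_repair

vocab = AminoAcidVocabulary.default()
truth = Peptide.from_string("GASPVK")
masses = vocab.mass_array()

# a sloppy "model output": confident everywhere except position 3,
# where it prefers N (114.043) over the true P (97.053)
rng = np.random.default_rng(0)
T = len(truth)
probs = np.full((T, len(vocab)), 0.01)
for t, tok in enumerate(truth.tokens):
    probs[t, vocab.id_of(tok)] = 5.0
probs[3, vocab.id_of("P")] = 1.0
probs[3, vocab.id_of("N")] = 4.0
probs /= probs.sum(axis=1, keepdims=True)
logprobs = np.log(probs)

argmax = vocab.decode(probs.argmax(axis=1))
target = peptide_mass(truth, vocab)
window = mass_window(target, tol_ppm=20)
print(f"true peptide     : {truth} ({target:.4f} Da)")
print(f"argmax peptide   : {argmax} ({peptide_mass(argmax, vocab):.4f} Da)"
      f"  -> outside [{window.L:.4f}, {window.U:.4f}]")

allowed = np.ones(len(vocab), dtype=bool)
allowed[vocab.unk_id] = False
ids = knapsack_repair(
    logprobs, masses, (window.L - WATER_MASS, window.U - WATER_MASS),
    allowed=allowed,
)
repaired = vocab.decode(ids)
print(f"repaired peptide : {repaired} ({peptide_mass(repaired, vocab):.4f} Da)"
      "  -> inside the window")
print(
    "\nThe solver keeps every confident residue and swaps the one position\n"
    "whose substitution restores mass consistency at the least probability cost."
)
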