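"""Generate a small annotated synthetic HCD corpus and inspect one spectrum.

The generator emits theoretical b/y fragment ladders of tryptic-like peptides;
with the default (noiseless) settings every peak is a real fragment ion and
the precursor m/z is exactly consistent with the peptide mass.
"""

import numpy as np

from pepflow import (
    AminoAcidVocabulary,
    SimulationConfig,
    peptide_mass,
    precursor_neutral_mass,
    simulate_dataset,
)

vocab = AminoAcidVocabulary.default()
spectra = simulate_dataset(SimulationConfig(n_peptides=5, seed=42), vocab)

for sp in spectra:
    m = precursor_neutral_mass(sp.precursor_mz, sp.precursor_charge)
    print(
        f"{sp.spectrum_id}: {sp.annotation} "
        f"({len(sp.annotation)} residues, {sp.n_peaks} peaks, "
        f"neutral mass {m:.4f} Da)"
    )

sp = spectra[0]
print("\nFirst spectrum peak ladder (m/z, intensity):")
for mz, inten in zip(sp.mz, sp.intensity):
    print(f"  {mz:10.4f}  {inten:8.4f}")
print(
    "\nPrecursor neutral mass equals the peptide monoisotopic mass "
    f"to {abs(precursor_neutral_mass(sp.precursor_mz, sp.precursor_charge) - peptide_mass(sp.annotation, vocab)):.2e} Da."
)
print("Peak count is 2(T-1): one b and one y ion per backbone bond.")
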