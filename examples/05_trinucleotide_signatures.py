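"""Trinucleotide error spectra and non-negative signature refitting.

Builds a 96-channel spectrum from simulated error events with their +/-1 bp
reference context, then refits it against a small synthetic signature matrix
(COSMIC-style, columns summing to 1) with non-negative least squares.
"""

import numpy as np
import pandas as pd

from bgerr.profiling import TrinucSpectrum, refit_signatures, spectrum_channels, trinuc_spectrum
from bgerr.synthetic import cfdna_reads_preset, simulate_reads

dataset = simulate_reads(cfdna_reads_preset(n_fragments=8000, n_samples=1),
                         None, seed=41)
reference = {dataset.ledger.chrom: dataset.ledger.reference}

events = dataset.ledger.events.query("sample_id == 'cf1'")
errors = [(dataset.ledger.chrom, int(r.pos), r.base_from, r.base_to)
          for r in events.itertuples()]
spectrum = trinuc_spectrum(errors, reference)
print(f"spectrum built from {int(spectrum.counts.sum())} error events "
      f"({spectrum.n_dropped_edge} dropped at contig edges)")
top = spectrum.fractions.sort_values(ascending=False).head(5)
print("top channels:")
for channel, frac in top.items():
    print(f"  {channel}: {100 * frac:.1f}%")

# synthetic signatures: one deamination-like (C>T-heavy), one flat
rng = np.random.default_rng(0)
channels = spectrum_channels()
deam = pd.Series(0.0, index=channels)
deam[[c for c in channels if "[C>T]" in c]] = 1.0
deam /= deam.sum()
flat = pd.Series(1.0 / 96, index=channels)
signatures = pd.DataFrame({"deamination-like": deam, "flat": flat})

weights = refit_signatures(spectrum, signatures)
print("\nNNLS refit weights (fractions of total):")
for name, w in weights.items():
    print(f"  {name}: {w:.2f}")
print("\nThe cfDNA-like preset's C>T/G>A excess loads onto the "
      "deamination-like signature; the uniform background loads onto flat.")
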