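"""Tandem-MS scoring on synthetic spectra with a planted topology.

A synthetic protein gets a random perfect-matching disulfide topology;
one noisy MS/MS spectrum is simulated per bonded peptide pair.  Each
spectrum is scored against every candidate pair whose linked mass fits
the precursor, and the per-bond scores feed a maximum-weight matching
that reconstructs the global topology.
"""

from ssfuse import MSConfig, enumerate_pairs, global_topology
from ssfuse.ms import score_spectrum, trim_search_space
from ssfuse.synth import SimConfig, generate, synth_spectra

sim = SimConfig(n_proteins=1, seed=7, n_cysteines_min=4, n_cysteines_max=6)
(protein,), topologies, _ = generate(sim)
planted = topologies[protein.id]
print(f"{protein.id}: {protein.n_cysteines} cysteines, planted topology "
      + ", ".join(str(b) for b in planted))

pairs = enumerate_pairs(protein, "trypsin", missed_cleavages=1)
masses = sorted(p.mass for p in pairs)
trimmed = trim_search_space(masses, epsilon=1e-3)
print(f"candidate disulfide-bonded pairs: {len(pairs)} "
      f"({len(masses)} masses, {len(trimmed)} after trimming at eps=1e-3)")

spectra = synth_spectra(protein, planted, noise_fraction=0.3, seed=7)
best = {}
for spectrum in spectra:
    for rep in score_spectrum(protein, spectrum, pairs, MSConfig()):
        if rep.bond not in best or rep.pp > best[rep.bond].pp:
            best[rep.bond] = rep

print("\nper-bond best scores (VS = matched-intensity %, pp = -log10 chance):")
for b, rep in sorted(best.items(), key=lambda kv: -kv[1].pp)[:6]:
    mark = "*" if b in planted else " "
    print(f" {mark} {b}: VS={rep.vs_score:5.1f}  pp={rep.pp:6.1f}  "
          f"pp2={rep.pp2:4.1f}  precursor={rep.precursor_mass:.1f} Da")

topology = global_topology({b: r.pp for b, r in best.items()})
print("\nmaximum-weight matching:", ", ".join(str(b) for b in topology))
print("planted bonds recovered:",
      len(set(topology.bonds) & planted.bonds), "of", len(planted))
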