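"""Simulate the synthetic H&E study cohort and write it to disk.

Generates the scaled-down two-class cohort (10 responders / 10
non-responders, one 144 px tile each, 2 px nuclear-radius class effect)
with ground-truth masks, and reports its composition.
"""

from pathlib import Path

from pathomics.experiments import small_cohort_spec
from pathomics.synthetic import generate_cohort, write_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main(seed: int = 7, effect_px: float = 2.0):
    spec = small_cohort_spec(effect_px=effect_px, seed=seed)
    cohort = generate_cohort(spec)
    manifest = write_cohort(cohort, OUT)
    n_tiles = sum(len(c.tiles) for c in cohort.cases)
    n_nuclei = sum(int(t.nuclei_mask.max()) for c in cohort.cases
                   for _, t in c.tiles)
    print(f"cohort: {spec.n_responders} responders + "
          f"{spec.n_nonresponders} non-responders, {n_tiles} tiles, "
          f"{n_nuclei} nuclei (effect {effect_px} px, seed {seed})")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
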