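"""Generate the synthetic study colony: tracks, landscape, survey, isotopes.

Writes fixes.csv, mask.geojson, survey.csv and isotopes.csv under
results/study/ and prints the realized trip mix.
"""

from common import study_pipeline


def main():
    pipe = study_pipeline()
    pipe.run_simulate()
    truth = pipe.sim_truth
    mix = truth["destination"].value_counts()
    print(f"simulated {truth['individual_id'].nunique()} individuals, "
          f"{len(truth)} trips")
    for dest, n in mix.items():
        print(f"  {dest}: {n} trips ({100 * n / len(truth):.1f}%)")
    print(f"outputs in {pipe.outdir}")


if __name__ == "__main__":
    main()
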