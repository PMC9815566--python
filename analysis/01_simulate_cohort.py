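"""Generate the synthetic BRAO cohort the downstream analyses run on.

Draws a cohort with the study's structure (17 patients, 1-5 scans each over
days 0-1040, %-scale noise SD 24 around the decay truth y0=-9.5,
plateau=-55.7, k=0.01/day) and writes the thickness table plus the
ground-truth ledger under results/cohort/.
"""

from pathlib import Path

from braotrial import CohortParams, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main(seed: int = 20240901) -> None:
    params = CohortParams(seed=seed)
    cohort = generate_cohort(params)
    records_path, truth_path = cohort.write(OUT)
    n_scans = len(cohort.truth)
    n_patients = cohort.truth["patient_id"].nunique()
    print(f"cohort: {n_patients} patients, {n_scans} affected-eye scans, "
          f"days {cohort.truth['day'].min()}-{cohort.truth['day'].max()}")
    print(f"wrote {records_path} ({len(cohort.records)} rows) and {truth_path}")


if __name__ == "__main__":
    main()
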