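"""Simulate the cohort and write the raw EDF fixtures.

Draws the three groups (HC, early-stage PD, late-stage PD) with their
clinical score distributions and amplitude-modulated oscillators, then
writes one EDF per subject per condition plus a metadata table.
"""

from _common import parse_config, stage_dir

from holospect.synthetic import simulate_cohort, write_fixture


def main() -> None:
    config = parse_config(__doc__)
    subjects, metadata = simulate_cohort(config.cohort)
    out = stage_dir(config, "fixtures")
    written = write_fixture(subjects, metadata, out)
    print(f"wrote {len(written)} files to {out}")
    print(metadata.groupby("group")["subject_id"].count().to_string())
    score = config.cohort.score_name
    print(f"\n{score} by group:")
    print(metadata.groupby("group")[score].agg(["mean", "std"]).round(2).to_string())


if __name__ == "__main__":
    main()
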