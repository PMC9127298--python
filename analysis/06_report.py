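"""Collate the stage outputs into a single summary report.

Reads the cluster tables and classification metrics produced by the
earlier scripts and writes ``summary.md`` under the output directory.
"""

from pathlib import Path

import pandas as pd
from _common import parse_config, stage_dir


def main() -> None:
    config = parse_config(__doc__)
    out = Path(config.out_dir)
    lines = ["# Analysis summary", ""]

    fixtures = out / "fixtures" / "metadata.tsv"
    if fixtures.exists():
        meta = pd.read_csv(fixtures, sep="\t")
        lines += ["## Cohort", "", meta.groupby("group")["subject_id"]
                  .count().to_frame("n").to_markdown(), ""]

    stats_dir = stage_dir(config, "stats")
    for table in sorted(stats_dir.glob("clusters_*.tsv")):
        df = pd.read_csv(table, sep="\t")
        lines += [f"## {table.stem}", ""]
        if df.empty:
            lines += ["No suprathreshold clusters.", ""]
        else:
            top = (
                df.groupby("cluster")
                .agg(cells=("channel", "size"), mass=("mass", "first"),
                     p_value=("p_value", "first"))
                .sort_values("p_value")
                .head(10)
            )
            lines += [top.round(4).to_markdown(), ""]

    metrics = out / "classify" / "metrics.tsv"
    if metrics.exists():
        df = pd.read_csv(metrics, sep="\t")
        lines += ["## Classification", "", df.round(3).to_markdown(index=False), ""]

    report = out / "summary.md"
    report.write_text("\n".join(lines))
    print(f"wrote {report}")
    print("\n".join(lines))


if __name__ == "__main__":
    main()
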