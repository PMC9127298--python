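"""Run the whole pipeline in one process (equivalent to scripts 01-05).

Uses ``holospect.pipeline.run_pipeline``, which additionally writes a
manifest with SHA-256 content hashes of every stage output; a rerun with
the same configuration produces byte-identical files.
"""

import json

from _common import parse_config

from holospect.pipeline import run_pipeline


def main() -> None:
    config = parse_config(__doc__)
    manifest = run_pipeline(config)
    n = sum(len(v) for v in manifest["stages"].values())
    print(f"pipeline complete: {n} output files under {config.out_dir}")
    print(json.dumps({k: len(v) for k, v in manifest["stages"].items()}, indent=2))


if __name__ == "__main__":
    main()
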