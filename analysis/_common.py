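"""Shared helpers for the numbered analysis scripts."""

from __future__ import annotations

import argparse
from pathlib import Path

from holospect.pipeline import PipelineConfig, load_config

HERE = Path(__file__).resolve().parent
DEFAULT_CONFIG = HERE / "config_demo.json"


def parse_config(description: str) -> PipelineConfig:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument(
        "--config", default=str(DEFAULT_CONFIG),
        help="JSON pipeline configuration (default: the demo config)",
    )
    parser.add_argument(
        "--out", default=None,
        help="override the configured output directory",
    )
    args = parser.parse_args()
    config = load_config(args.config)
    if args.out is not None:
        config.out_dir = args.out
    return config


def stage_dir(config: PipelineConfig, name: str) -> Path:
    d = Path(config.out_dir) / name
    d.mkdir(parents=True, exist_ok=True)
    return d
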