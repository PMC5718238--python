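"""Structured comparison report and its on-disk forms.

The report is regenerable bit-identically from (config, seed): the
provenance block records both plus the package version and config hash.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
import json
from pathlib import Path

import numpy as np

SCHEMA_VERSION = 1


@dataclass
class ComparisonReport:
    provenance: dict
    tally: dict
    peak_epidermal: dict
    peak_follicle: dict
    rise_epidermal: dict
    rise_follicle: dict
    excess_percent: dict
    exceeds_threshold: dict
    threshold: float
    pulse_trains: dict
    schema_version: int = SCHEMA_VERSION
    traces: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("traces")
        return d


def write_report(report: ComparisonReport, outdir) -> Path:
    """Write report.json plus one (time_s, T_epidermis_C, T_follicle_C)
    trace file per category; returns the report path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    try:
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        for cat, tr in report.traces.items():
            np.savetxt(outdir / f"trace_{cat}.tsv",
                       np.column_stack([tr["times"], tr["epidermal"], tr["follicle"]]),
                       fmt="%.6e", delimiter="\t",
                       header="time_s\tT_epidermis_C\tT_follicle_C")
    except OSError as exc:
        raise OSError(f"failed to write report under {outdir}: {exc}") from exc
    return path


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
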