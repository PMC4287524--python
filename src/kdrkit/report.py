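"""Rendering of a ReportBundle as text, CSV or JSON.

Internal values stay full precision; rounding to the conventional printed
precision (3 decimals for frequencies and p-values, 2 for odds ratios and
their bounds) happens only in the text/CSV renderers. JSON keeps full
precision so a round-trip parse reproduces the values exactly.
"""

from __future__ import annotations

import io as _io
import json

import pandas as pd

from .datatypes import ReportBundle
from .errors import UsageError

_SECTIONS = ("allele_frequencies", "hwe", "association", "haplotypes", "ld")

_ROUND = {
    "p_wild": 3, "p_mut": 3, "p_value": 3, "statistic": 3,
    "odds_ratio": 2, "ci_low": 2, "ci_high": 2, "p_fisher": 4,
    "f_11": 3, "f_12": 3, "f_21": 3, "f_22": 3,
    "D": 4, "D_prime": 3, "r_squared": 3, "chi_square": 2,
    "corrected_pct": 2,
}


def _frame(rows: list[dict], rounded: bool) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if rounded:
        for col, nd in _ROUND.items():
            if col in df.columns:
                df[col] = df[col].round(nd)
    return df


def render_report(bundle: ReportBundle, format: str = "text") -> str:
    """Render every populated section of the bundle; deterministic output."""
    if format not in ("text", "csv", "json"):
        raise UsageError(f"unknown report format {format!r}")

    if format == "json":
        payload = {"metadata": bundle.metadata}
        for s in _SECTIONS:
            payload[s] = getattr(bundle, s)
        return json.dumps(payload, indent=2, sort_keys=True)

    chunks = []
    if format == "text":
        chunks.append("kdrkit analysis report")
        for k in sorted(bundle.metadata):
            chunks.append(f"  {k}: {bundle.metadata[k]}")
        for s in _SECTIONS:
            rows = getattr(bundle, s)
            if not rows:
                continue
            chunks.append("")
            chunks.append(f"== {s.replace('_', ' ')} ==")
            chunks.append(_frame(rows, rounded=True).to_string(index=False))
        return "\n".join(chunks) + "\n"

    # csv: one block per section, prefixed with a comment header
    out = _io.StringIO()
    out.write("# kdrkit analysis report\n")
    for k in sorted(bundle.metadata):
        out.write(f"# {k}: {bundle.metadata[k]}\n")
    for s in _SECTIONS:
        rows = getattr(bundle, s)
        if not rows:
            continue
        out.write(f"# section: {s}\n")
        _frame(rows, rounded=True).to_csv(out, index=False)
    return out.getvalue()
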