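"""Plain-text I/O for censored concentration samples.

Format: a first header line ``lod,<value>`` followed by a two-column CSV
``value,censored`` where the flag is 0/1.  The synthetic generator writes
exactly this format, so generated fixtures are indistinguishable from real
inputs to the fitting code.
"""

from __future__ import annotations

from .distributions import CensoredSample
from .errors import ConfigError

__all__ = ["read_censored_csv", "write_censored_csv"]


def write_censored_csv(sample: CensoredSample, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"lod,{sample.lod:.12g}\n")
        fh.write("value,censored\n")
        for v, c in zip(sample.values, sample.censored):
            fh.write(f"{v:.12g},{int(c)}\n")


def read_censored_csv(path) -> CensoredSample:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].lower().startswith("lod,"):
        raise ConfigError(f"{path}: line 1 must be an 'lod,<value>' header")
    try:
        lod = float(lines[0].split(",", 1)[1])
    except ValueError as exc:
        raise ConfigError(f"{path}: line 1: unparseable LOD") from exc
    if len(lines) < 2 or lines[1].lower().replace(" ", "") != "value,censored":
        raise ConfigError(f"{path}: line 2 must be the 'value,censored' header")
    values, flags = [], []
    for i, ln in enumerate(lines[2:], start=3):
        parts = ln.split(",")
        if len(parts) != 2:
            raise ConfigError(f"{path}: line {i}: expected 'value,censored'")
        try:
            values.append(float(parts[0]))
            flags.append(bool(int(parts[1])))
        except ValueError as exc:
            raise ConfigError(f"{path}: line {i}: unparseable row {ln!r}") from exc
    return CensoredSample(values=values, censored=flags, lod=lod)
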