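"""Pipeline configuration.

Defaults follow the published hnRNP A1 iCLIP protocol: 9-nt 5' barcode
``RRRIIIIRR`` (R = random/UMI base, I = sample identifier base), reads kept at
>= 20 nt after trimming, crosslink sites extended by 10 nt to either side,
peak FDR threshold 0.10, 1-kb superlocal background windows, k-mer lengths
{6,7,8} for motif enrichment, a uniform 0.25 base background for motif
scoring, and a 10-40 nt intronic window downstream of 5' splice sites for SSO
target selection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

DEFAULT_ADAPTER = "AGATCGGAAGAGC"


@dataclass
class PipelineConfig:
    barcode_scheme: str = "RRRIIIIRR"
    adapter: str = DEFAULT_ADAPTER
    min_read_length: int = 20
    quality_threshold: int = 20
    adapter_min_overlap: int = 3
    adapter_max_mismatch: int = 1
    crosslink_flank: int = 10
    peak_fdr: float = 0.10
    n_permutations: int = 1000
    superlocal_window: int = 1000
    kmer_lengths: tuple[int, ...] = (6, 7, 8)
    background_base_freq: float = 0.25
    scoring_pseudocount: float = 0.001
    sso_window: tuple[int, int] = (10, 40)
    sso_length_range: tuple[int, int] = (18, 25)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.barcode_scheme) - {"R", "I"}:
            raise ValueError("barcode_scheme must be a string over {R, I}")
        if not 0 < self.peak_fdr < 1:
            raise ValueError("peak_fdr must be a fraction in (0, 1)")
        if not 0 < self.background_base_freq < 1:
            raise ValueError("background_base_freq must be in (0, 1)")
        lo, hi = self.sso_window
        if lo > hi or lo < 0:
            raise ValueError("sso_window must be (min, max) with 0 <= min <= max")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat ``key = value`` config file; unknown keys are rejected."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _parse_value(value, fields[key].type)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


def _parse_value(text: str, annotation: object) -> object:
    ann = str(annotation)
    if "tuple" in ann:
        return tuple(int(v) for v in text.replace("(", "").replace(")", "").split(","))
    if ann in ("int", "<class 'int'>"):
        return int(text)
    if ann in ("float", "<class 'float'>"):
        return float(text)
    return text
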