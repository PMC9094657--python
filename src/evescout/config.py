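"""Screen configuration: every tunable threshold with a documented default.

Config files are plain text `key = value` lines ('#' starts a comment).
Unknown keys are rejected so silent typos cannot change a screen.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class ScreenConfig:
    # reproducibility
    seed: int = 1

    # inputs / outputs (optional; CLI flags override)
    genome_fasta: str = ""
    query_fasta: str = ""
    out_dir: str = "evescout_out"

    # translated homology search (locus seeding)
    gap_open: float = 11.0          # affine gap open (BLOSUM62 convention)
    gap_extend: float = 1.0
    min_bits: float = 50.0          # minimum bit score to seed a locus
    min_aligned: int = 80           # minimum aligned residues
    merge_gap: int = 1000           # nt; same-frame hits closer than this merge
    karlin_lambda: float = 0.267    # gapped Karlin-Altschul constants
    karlin_k: float = 0.041

    # locus extraction around merged envelope hits; Env sits near the 3' LTR
    # so the 5'-ward flank must bridge Gag-Pol back to the 5' repeat
    flank_upstream: int = 8000
    flank_downstream: int = 2000

    # terminal repeat detection
    ltr_flank_window: int = 3000
    ltr_min_len: int = 100
    ltr_max_len: int = 1500
    ltr_match: float = 2.0
    ltr_mismatch: float = -3.0
    ltr_gap_open: float = 5.0
    ltr_gap_extend: float = 2.0
    ltr_min_score: float = 100.0
    intact_threshold: float = 95.0  # percent identity for an "intact" pair
    end_tolerance: int = 20         # nt; repeat-to-contig-end slack for "truncated"

    # polyprotein integrity
    min_codons: int = 1500
    min_orf_coverage: float = 0.8
    motif_full_scan: bool = False   # scan whole polyprotein, not middle third
    pol_motif_back: int = 150       # residues from motif back to Pol start

    # envelope architecture
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_len: int = 17

    @classmethod
    def from_file(cls, path) -> "ScreenConfig":
        cfg = cls()
        known = {f.name: f for f in fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, val = (s.strip() for s in line.partition("="))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                setattr(cfg, key, _coerce(val, known[key].type, key))
        return cfg

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_text())


def _coerce(value: str, ftype, key: str):
    t = str(ftype)
    try:
        if "bool" in t:
            if value.lower() in {"true", "1", "yes"}:
                return True
            if value.lower() in {"false", "0", "no"}:
                return False
            raise ValueError
        if "int" in t:
            return int(value)
        if "float" in t:
            return float(value)
        return value
    except ValueError as exc:
        raise ValueError(f"config key {key!r}: cannot parse {value!r}") from exc


def default_config_text() -> str:
    return ScreenConfig().to_text()
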