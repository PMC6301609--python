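"""Corrections that place raw measurements on a common basis before modelling.

Two families of adjustment:

* **Suess-effect correction** — atmospheric CO2 d13C has declined since ~1860
  (fossil-fuel carbon), so modern tissue d13C must be raised to a
  pre-industrial-equivalent value before comparison with archaeological
  material. The terrestrial correction for a given collection year is
  ``preindustrial_ref - mean_d13C_CO2(year)`` (a positive quantity for any
  post-industrial year); the marine correction is that value scaled by a
  constant (default 0.65) reflecting the ocean's damped response. Corrections
  are *added* to the sample's d13C. d15N is never Suess-corrected.

* **Tissue offsets** — fixed isotopic spacings between tissues (e.g.
  collagen-keratin, bone collagen-flesh) applied additively per element so
  all values refer to a common tissue basis.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .data_io import ARCHAEOLOGICAL, AtmosphericSeries, ConsumerRecord, IsotopeSample

#: Onset of the atmospheric d13C decline; samples collected from this year on
#: (equivalently, "less than ~200 years old") receive the Suess correction.
SUESS_ONSET_YEAR = 1860


@dataclass
class SuessConfig:
    preindustrial_ref: float = -6.48  # permil, pre-industrial atmospheric CO2 d13C
    marine_scale: float = 0.65
    age_threshold_years: int = 200

    def __post_init__(self) -> None:
        if not (0.0 < self.marine_scale <= 1.0):
            raise ValueError("marine_scale must be in (0, 1]")
        if self.age_threshold_years <= 0:
            raise ValueError("age_threshold_years must be positive")


@dataclass
class TissueOffset:
    """Additive per-element offset converting one tissue basis to another.

    Sign convention: the offset is defined as target-tissue minus
    source-tissue (epsilon notation), so converting a measurement *to* the
    target basis adds the offset as stored. E.g. collagen-keratin offsets of
    (-0.3, +0.4) permil mean hair values map to collagen-equivalent by adding
    -0.3 to d13C and +0.4 to d15N.
    """

    name: str
    tissue_from: str
    tissue_to: str
    d13C_offset: float
    d15N_offset: float
    taxon_pattern: str = "*"  # fnmatch pattern against the sample's taxon

    def __post_init__(self) -> None:
        if abs(self.d13C_offset) > 6.0 or abs(self.d15N_offset) > 6.0:
            raise ValueError("offset magnitude exceeds 6 permil sanity bound")


#: Collagen-keratin spacing measured in Macaca mulatta, used to convert
#: primate hair values to a bone-collagen-equivalent basis.
COLLAGEN_KERATIN = TissueOffset(
    name="collagen_keratin", tissue_from="hair", tissue_to="bone collagen",
    d13C_offset=-0.3, d15N_offset=+0.4,
)


def read_offsets(path) -> list[TissueOffset]:
    """Load a tissue-offset config table (CSV)."""
    df = pd.read_csv(path)
    offsets = []
    for _, row in df.iterrows():
        offsets.append(TissueOffset(
            name=str(row["name"]), tissue_from=str(row["tissue_from"]),
            tissue_to=str(row["tissue_to"]),
            d13C_offset=float(row["d13C_offset"]),
            d15N_offset=float(row["d15N_offset"]),
            taxon_pattern=str(row.get("taxon_pattern", "*")),
        ))
    return offsets


def suess_correction(year: int, habitat: str, series: AtmosphericSeries,
                     cfg: SuessConfig | None = None) -> float:
    """Additive d13C Suess correction (permil) for a collection year and habitat."""
    cfg = cfg or SuessConfig()
    if year not in series:
        raise KeyError(f"year {year} not present in atmospheric series")
    terrestrial = cfg.preindustrial_ref - series.value(year)
    if habitat == "marine":
        return cfg.marine_scale * terrestrial
    if habitat == "terrestrial":
        return terrestrial
    raise ValueError(f"unknown habitat {habitat!r}")


def apply_tissue_offset(sample, offset: TissueOffset):
    """Return a copy of the record with the offset added to both deltas.

    The input record is untouched, so the raw values remain available for
    audit; a tissue mismatch is an error, not a no-op.
    """
    if isinstance(sample, IsotopeSample) and sample.tissue != offset.tissue_from:
        raise ValueError(
            f"offset {offset.name} applies to tissue {offset.tissue_from!r}, "
            f"sample {sample.sample_id} has {sample.tissue!r}")
    corrected = replace(sample,
                        d13C=sample.d13C + offset.d13C_offset,
                        d15N=sample.d15N + offset.d15N_offset)
    if isinstance(corrected, IsotopeSample):
        corrected = replace(corrected, tissue=offset.tissue_to)
    return corrected


@dataclass
class Adjustment:
    sample_id: str
    kind: str  # "suess" or the offset name
    d13C_delta: float
    d15N_delta: float


def apply_corrections(samples: Sequence[IsotopeSample], series: AtmosphericSeries,
                      offsets: Sequence[TissueOffset] = (),
                      cfg: SuessConfig | None = None):
    """Apply tissue offsets then Suess corrections to a source collection.

    Returns ``(corrected_samples, audit_log)`` where the audit log records one
    :class:`Adjustment` per applied correction. Archaeological samples are
    exempt from the Suess correction; a modern sample (collection_year >=
    1860) whose year is missing from the series is an error listing the ids.
    """
    cfg = cfg or SuessConfig()
    corrected: list[IsotopeSample] = []
    audit: list[Adjustment] = []

    missing_years: list[str] = []
    for s in samples:
        rec = s
        for off in offsets:
            if rec.tissue == off.tissue_from and fnmatch.fnmatch(rec.taxon, off.taxon_pattern):
                rec = apply_tissue_offset(rec, off)
                audit.append(Adjustment(s.sample_id, off.name,
                                        off.d13C_offset, off.d15N_offset))
        year = rec.collection_year
        if year != ARCHAEOLOGICAL and int(year) >= SUESS_ONSET_YEAR:
            if int(year) not in series:
                missing_years.append(s.sample_id)
                continue
            corr = suess_correction(int(year), rec.habitat, series, cfg)
            rec = replace(rec, d13C=rec.d13C + corr)
            audit.append(Adjustment(s.sample_id, "suess", corr, 0.0))
        corrected.append(rec)
    if missing_years:
        raise KeyError(
            "modern sample(s) with collection year absent from atmospheric "
            f"series: {missing_years}")
    return corrected, audit


def corrections_frame(raw: Sequence[IsotopeSample],
                      corrected: Sequence[IsotopeSample]) -> pd.DataFrame:
    """Side-by-side raw and corrected deltas for export/audit."""
    rows = []
    by_id = {s.sample_id: s for s in corrected}
    for s in raw:
        c = by_id.get(s.sample_id)
        rows.append({
            "sample_id": s.sample_id, "group": s.group,
            "d13C_raw": s.d13C, "d15N_raw": s.d15N,
            "d13C_corrected": c.d13C if c else float("nan"),
            "d15N_corrected": c.d15N if c else float("nan"),
        })
    return pd.DataFrame(rows)
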