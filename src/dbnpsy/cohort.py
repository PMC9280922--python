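"""Cohort assembly: item catalog, binarization, syndrome flags, eligibility.

Two-wave panels of binary indicators are the raw material of the temporal
network analysis: 23 self-rated psychological symptom items (6 somatic and
6 anxious-depressive SPHERE-12 items, 5 hypomanic items, 6 psychotic-like
items), 2 role-functioning items, 3 substance-use items, a social-support
item coded in the risk direction (1 = lacks a confidante), and one static
twin/non-twin covariate.  This module reads delimited panels, applies the
binarization rules for substance use and days-out-of-role counts, derives
the three subthreshold-syndrome flags (depression-like, hypomanic-like and
psychotic-like experiences) and applies the eligibility filters that define
the two analysis cohorts.

Exact questionnaire item wordings are not part of the public record for
this instrument battery; the packaged default catalog therefore uses
semantic placeholder identifiers (one per item role).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .nodes import STATIC, W1, W2, tag

# --------------------------------------------------------------------------
# Item catalog
# --------------------------------------------------------------------------

DOMAINS = (
    "soma6",
    "psych6",
    "hypomanic",
    "psychotic",
    "functioning",
    "substance",
    "social_support",
    "static",
)

#: domains whose items vary by wave (everything except the static covariate)
DYNAMIC_DOMAINS = tuple(d for d in DOMAINS if d != "static")

#: required item counts for the symptom domains
_DOMAIN_SIZES = {"soma6": 6, "psych6": 6, "hypomanic": 5, "psychotic": 6}

#: syndrome-flag node identifiers (depression-, hypomanic-, psychotic-like)
SYNDROME_ITEMS = ("dle", "hmle", "ple")


@dataclass(frozen=True)
class CatalogItem:
    item_id: str
    label: str
    domain: str
    scale: str


@dataclass(frozen=True)
class ItemCatalog:
    """The full node set of the analysis, partitioned into domains."""

    items: tuple[CatalogItem, ...]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids in catalog: {dupes}")
        for it in self.items:
            if it.domain not in DOMAINS:
                raise ValueError(f"unknown domain {it.domain!r} for item {it.item_id!r}")
        for domain, size in _DOMAIN_SIZES.items():
            n = len(self.domain_items(domain))
            if n != size:
                raise ValueError(f"catalog must contain exactly {size} {domain} items, got {n}")

    def domain_items(self, domain: str) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items if it.domain == domain)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def dynamic_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items if it.domain != "static")

    @property
    def static_ids(self) -> tuple[str, ...]:
        return self.domain_items("static")

    def items_for_wave(self, wave: str) -> tuple[str, ...]:
        """Columns expected in a single-wave panel (static items ride with W1)."""
        if wave == W1:
            return self.dynamic_ids + self.static_ids
        if wave == W2:
            return self.dynamic_ids
        raise ValueError(f"unknown wave {wave!r}")


def _mk(domain: str, scale: str, *ids: str) -> list[CatalogItem]:
    return [CatalogItem(i, i.replace("_", " "), domain, scale) for i in ids]


def default_catalog() -> ItemCatalog:
    """The packaged 30-node catalog (identifiers are semantic placeholders)."""
    items: list[CatalogItem] = []
    items += _mk(
        "soma6", "SPHERE-12 SOMA-6",
        "hypersomnia", "anergia", "somatic_pain", "fatigue",
        "impaired_sleep_quality", "prolonged_tiredness",
    )
    items += _mk(
        "psych6", "SPHERE-12 PSYCH-6",
        "feeling_overwhelmed", "hopelessness", "impaired_concentration",
        "feeling_stressed", "irritability", "feeling_nervous",
    )
    items += _mk(
        "hypomanic", "hypomania self-rating",
        "feeling_elated", "increased_self_esteem", "decreased_need_for_sleep",
        "pressured_speech", "increased_activity",
    )
    items += _mk(
        "psychotic", "CAPE-adapted",
        "feeling_threatened", "thoughts_not_own", "heard_voices",
        "visual_hallucinations", "thought_broadcasting", "delusional_mood",
    )
    items += _mk("functioning", "WHO-DAS", "days_out_of_role", "days_in_bed")
    items += _mk("substance", "ASSIST", "tobacco", "alcohol", "cannabis")
    # 1 = answered "no" to the confidante item (risk direction)
    items += _mk("social_support", "Kessler support", "no_confidante")
    items += _mk("static", "registry", "twin_status")
    return ItemCatalog(tuple(items))


# --------------------------------------------------------------------------
# Panels
# --------------------------------------------------------------------------


@dataclass
class WavePanel:
    """Participant x item binary matrix for one wave.

    ``values`` is indexed by participant id with one column per (untagged)
    item id.  A catalog, when attached, fixes the expected column set.
    """

    values: pd.DataFrame
    wave: str
    catalog: ItemCatalog | None = None

    def __post_init__(self) -> None:
        if self.wave not in (W1, W2):
            raise ValueError(f"unknown wave {self.wave!r}")
        if self.values.index.has_duplicates:
            dupes = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate participant_id: {dupes}")
        self._validate_binary()
        if self.catalog is not None:
            expected = set(self.catalog.items_for_wave(self.wave))
            got = set(self.values.columns)
            missing = sorted(expected - got)
            unknown = sorted(got - expected)
            if missing:
                raise ValueError(f"panel is missing catalog items: {missing}")
            if unknown:
                raise ValueError(f"panel has columns not in the catalog: {unknown}")

    def _validate_binary(self) -> None:
        arr = self.values.to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary value {arr[r, c]!r} at participant "
                f"{self.values.index[r]!r}, column {self.values.columns[c]!r}"
            )

    @property
    def participants(self) -> pd.Index:
        return self.values.index

    @property
    def n(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return self.n


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def _coerce_binary(df: pd.DataFrame, context: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        s = pd.to_numeric(df[col], errors="coerce")
        bad = s.isna() | ~s.isin((0, 1))
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"{context}: non-binary value {df[col].loc[row]!r} "
                f"at row {row!r}, column {col!r}"
            )
        out[col] = s.astype(np.int8)
    return pd.DataFrame(out, index=df.index)


def load_panel(path: str | Path, catalog: ItemCatalog, wave: str = W1) -> WavePanel:
    """Read a single-wave delimited panel (participant_id + item columns)."""
    raw = _read_delimited(path)
    if "participant_id" not in raw.columns:
        raise ValueError("header must contain a participant_id column")
    raw = raw.set_index("participant_id")
    if raw.index.has_duplicates:
        dupes = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValueError(f"duplicate participant_id: {dupes}")
    expected = set(catalog.items_for_wave(wave))
    unknown = sorted(set(raw.columns) - expected)
    if unknown:
        raise ValueError(f"unknown columns not in catalog: {unknown}")
    missing = sorted(expected - set(raw.columns))
    if missing:
        raise ValueError(f"missing catalog item columns: {missing}")
    values = _coerce_binary(raw[list(catalog.items_for_wave(wave))], str(path))
    return WavePanel(values=values, wave=wave, catalog=catalog)


def load_cohort(path: str | Path, catalog: ItemCatalog) -> tuple[WavePanel, WavePanel]:
    """Read a two-wave cohort file in either accepted dialect.

    Wide: one row per participant, columns ``item@W1`` / ``item@W2`` plus
    untagged static columns.  Long: one row per participant per wave with a
    ``wave`` column and untagged item columns (static items on the W1 rows).
    """
    raw = _read_delimited(path)
    if "participant_id" not in raw.columns:
        raise ValueError("header must contain a participant_id column")
    if "wave" in raw.columns:  # long dialect
        w1 = raw[raw["wave"] == W1].drop(columns="wave").set_index("participant_id")
        w2 = raw[raw["wave"] == W2].drop(columns="wave").set_index("participant_id")
        w2 = w2[[c for c in w2.columns if c in set(catalog.dynamic_ids)]]
    else:  # wide dialect
        raw = raw.set_index("participant_id")
        w1_cols = {f"{i}@{W1}": i for i in catalog.dynamic_ids}
        w2_cols = {f"{i}@{W2}": i for i in catalog.dynamic_ids}
        static_cols = {i: i for i in catalog.static_ids}
        known = set(w1_cols) | set(w2_cols) | set(static_cols)
        unknown = sorted(set(raw.columns) - known)
        if unknown:
            raise ValueError(f"unknown columns not in catalog: {unknown}")
        w1 = raw[[c for c in raw.columns if c in w1_cols or c in static_cols]].rename(
            columns={**w1_cols, **static_cols}
        )
        w2 = raw[[c for c in raw.columns if c in w2_cols]].rename(columns=w2_cols)
    missing1 = sorted(set(catalog.items_for_wave(W1)) - set(w1.columns))
    missing2 = sorted(set(catalog.items_for_wave(W2)) - set(w2.columns))
    if missing1 or missing2:
        raise ValueError(f"missing catalog item columns: {sorted(missing1 + missing2)}")
    p1 = WavePanel(_coerce_binary(w1[list(catalog.items_for_wave(W1))], f"{path} (W1)"), W1, catalog)
    p2 = WavePanel(_coerce_binary(w2[list(catalog.items_for_wave(W2))], f"{path} (W2)"), W2, catalog)
    return p1, p2


def join_waves(panel_w1: WavePanel, panel_w2: WavePanel) -> pd.DataFrame:
    """Build the joint wave-tagged analysis frame over shared participants.

    Dynamic W1 items become ``item@W1``, W2 items ``item@W2``; static
    covariates keep their bare name.  Participants present in only one wave
    are dropped (they fail the completeness filter anyway).
    """
    shared = panel_w1.participants.intersection(panel_w2.participants)
    static = panel_w1.catalog.static_ids if panel_w1.catalog else ()
    w1_dyn = [c for c in panel_w1.values.columns if c not in static]
    left = panel_w1.values.loc[shared, w1_dyn].rename(columns=lambda c: tag(c, W1))
    if static:
        left = pd.concat([left, panel_w1.values.loc[shared, list(static)]], axis=1)
    right = panel_w2.values.loc[shared].rename(columns=lambda c: tag(c, W2))
    return pd.concat([left, right], axis=1)


# --------------------------------------------------------------------------
# Binarization rules
# --------------------------------------------------------------------------

#: ASSIST recent-use frequency ladder
ASSIST_CATEGORIES = ("never", "once_or_twice", "monthly", "weekly", "daily_or_almost_daily")

_SUBSTANCE_POSITIVE = {
    "tobacco": {"daily_or_almost_daily"},
    "alcohol": {"daily_or_almost_daily"},
    "cannabis": {"weekly", "daily_or_almost_daily"},
}


def binarize_substance(raw_category: str, substance: str) -> int:
    """Binarize an ASSIST frequency response.

    Tobacco and alcohol count as recent use only at daily (or almost daily)
    frequency; cannabis already at weekly frequency.
    """
    if substance not in _SUBSTANCE_POSITIVE:
        raise ValueError(f"unknown substance {substance!r}; expected one of "
                         f"{sorted(_SUBSTANCE_POSITIVE)}")
    if raw_category not in ASSIST_CATEGORIES:
        raise ValueError(f"unknown frequency category {raw_category!r}; expected one of "
                         f"{ASSIST_CATEGORIES}")
    return int(raw_category in _SUBSTANCE_POSITIVE[substance])


def binarize_days(count: int) -> int:
    """Any day out of role (or in bed) in the recall window counts."""
    if count < 0:
        raise ValueError(f"day count must be nonnegative, got {count}")
    return int(count >= 1)


# --------------------------------------------------------------------------
# Subthreshold syndromes
# --------------------------------------------------------------------------


def derive_syndromes(panel: WavePanel) -> pd.DataFrame:
    """Per-participant subthreshold-syndrome flags for one wave.

    * ``dle``  (depression-like):  >=3 of the 6 somatic items or >=2 of the
      6 anxious-depressive items;
    * ``hmle`` (hypomanic-like):   all 5 hypomanic items co-endorsed;
    * ``ple``  (psychotic-like):   >=2 of the 6 psychotic-like items.
    """
    if panel.catalog is None:
        raise ValueError("panel must carry an ItemCatalog to derive syndromes")
    cat = panel.catalog
    for domain in ("soma6", "psych6", "hypomanic", "psychotic"):
        missing = set(cat.domain_items(domain)) - set(panel.values.columns)
        if missing:
            raise ValueError(f"panel lacks {domain} items: {sorted(missing)}")
    v = panel.values
    soma = v[list(cat.domain_items("soma6"))].sum(axis=1)
    psych = v[list(cat.domain_items("psych6"))].sum(axis=1)
    hypo = v[list(cat.domain_items("hypomanic"))].sum(axis=1)
    psychotic = v[list(cat.domain_items("psychotic"))].sum(axis=1)
    return pd.DataFrame(
        {
            "dle": ((soma >= 3) | (psych >= 2)).astype(np.int8),
            "hmle": (hypo == 5).astype(np.int8),
            "ple": (psychotic >= 2).astype(np.int8),
        },
        index=v.index,
    )


# --------------------------------------------------------------------------
# Eligibility
# --------------------------------------------------------------------------


def build_eligibility_flags(
    panel_w1: WavePanel,
    panel_w2: WavePanel,
    cidi_diagnosis_w1: Mapping | pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-participant eligibility flag frame.

    ``complete_both_waves`` comes from panel membership, ``any_sts_w1`` from
    the derived syndrome flags, and ``cidi_diagnosis_w1`` is the externally
    supplied full-threshold diagnostic interview exclusion flag (default 0,
    i.e. no diagnosis).
    """
    everyone = panel_w1.participants.union(panel_w2.participants)
    flags = pd.DataFrame(index=everyone)
    shared = panel_w1.participants.intersection(panel_w2.participants)
    flags["complete_both_waves"] = flags.index.isin(shared).astype(np.int8)
    cidi = pd.Series(0, index=everyone, dtype=np.int8)
    if cidi_diagnosis_w1 is not None:
        supplied = pd.Series(cidi_diagnosis_w1)
        cidi.loc[supplied.index.intersection(everyone)] = supplied.astype(np.int8)
    flags["cidi_diagnosis_w1"] = cidi
    sts = pd.Series(0, index=everyone, dtype=np.int8)
    try:
        syn = derive_syndromes(panel_w1)
    except ValueError:
        # panel does not span the symptom domains (e.g. a reduced synthetic
        # node set); no syndrome can be asserted, so nobody is flagged
        warnings.warn("wave-1 panel cannot derive syndrome flags; any_sts_w1 set to 0",
                      stacklevel=2)
    else:
        sts.loc[syn.index] = syn.max(axis=1).astype(np.int8)
    flags["any_sts_w1"] = sts
    return flags


def apply_eligibility(
    panel_w1: WavePanel,
    panel_w2: WavePanel,
    flags: pd.DataFrame,
    mode: str = "primary",
) -> tuple[WavePanel, WavePanel, pd.DataFrame]:
    """Filter the paired panels down to an analysis cohort.

    ``primary`` keeps participants observed complete at both waves with no
    full-threshold diagnosis at wave 1; ``progression`` additionally drops
    anyone already carrying a subthreshold syndrome at wave 1.  Returns the
    filtered panels plus a roster of every participant with the kept flag
    and the (first applicable) exclusion reason.
    """
    if mode not in ("primary", "progression"):
        raise ValueError(f"unknown eligibility mode {mode!r}")
    everyone = panel_w1.participants.union(panel_w2.participants)
    flags = flags.reindex(everyone)
    reasons = []
    for pid in everyone:
        row = flags.loc[pid]
        if not bool(row.get("complete_both_waves", 0)):
            reasons.append("incomplete")
        elif bool(row.get("cidi_diagnosis_w1", 0)):
            reasons.append("cidi_diagnosis_w1")
        elif mode == "progression" and bool(row.get("any_sts_w1", 0)):
            reasons.append("sts_at_w1")
        else:
            reasons.append("")
    roster = pd.DataFrame(
        {"participant_id": everyone, "kept": [int(r == "") for r in reasons], "reason": reasons}
    ).reset_index(drop=True)
    kept = roster.loc[roster["kept"] == 1, "participant_id"]
    p1 = WavePanel(panel_w1.values.loc[kept], W1, panel_w1.catalog)
    p2 = WavePanel(panel_w2.values.loc[kept], W2, panel_w2.catalog)
    return p1, p2, roster
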