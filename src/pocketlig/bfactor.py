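"""Per-residue crystallographic B-factor profiles and region comparison.

B-factors index positional disorder in the lattice; comparing two crystals
(e.g. the same receptor bound to a fatty acid vs a thiazolidinedione)
requires normalization first, because overall B scales differ between
crystals. Region comparisons then make a sign call per named region
(helix 12, the H11-H12 loop, the H2-H3/beta-sheet region, ...) with an
explicit threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import AtomSet, Structure

__all__ = [
    "BFactorProfile",
    "RegionComparison",
    "residue_bfactor_profile",
    "normalize_profile",
    "compare_profiles",
    "DEFAULT_REGIONS",
]

BACKBONE_NAMES = {"N", "CA", "C", "O"}

# Default region residue ranges for the PPARgamma ligand-binding domain
# (author numbering); configurable — secondary-structure annotations vary.
DEFAULT_REGIONS: dict[str, list[tuple[int, int]]] = {
    "H12": [(466, 477)],
    "H11-H12 loop": [(455, 465)],
    "H2-H3/beta-sheet": [(264, 275), (338, 352)],
}


@dataclass
class BFactorProfile:
    """Ordered per-residue mean B (A^2), optionally backbone-only."""

    table: pd.DataFrame  # columns: chain, resnum, resname, b
    label: str = ""
    backbone_only: bool = False
    normalized: str | None = None  # None | "zscore" | "minmax"

    def __len__(self) -> int:
        return len(self.table)

    @property
    def values(self) -> np.ndarray:
        return self.table["b"].to_numpy()

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def residue_bfactor_profile(structure: Structure, sel: AtomSet,
                            backbone_only: bool = False,
                            label: str = "") -> BFactorProfile:
    """Per-residue mean of member-atom B-factors over a selection."""
    rows = []
    import warnings

    by_res: dict[tuple, list] = {}
    order: list[tuple] = []
    for a in sel.atoms:
        k = (a.chain_id, a.residue_number, a.residue_name)
        if k not in by_res:
            by_res[k] = []
            order.append(k)
        by_res[k].append(a)
    for k in order:
        atoms = by_res[k]
        if backbone_only:
            atoms = [a for a in atoms if a.name in BACKBONE_NAMES]
        if not atoms:
            warnings.warn(f"residue {k} empty after backbone filtering; skipped")
            continue
        rows.append({"chain": k[0], "resnum": k[1], "resname": k[2],
                     "b": float(np.mean([a.b_factor for a in atoms]))})
    return BFactorProfile(pd.DataFrame(rows, columns=["chain", "resnum", "resname", "b"]),
                          label=label, backbone_only=backbone_only)


def normalize_profile(profile: BFactorProfile, method: str = "zscore") -> BFactorProfile:
    """Normalize a profile (zscore: mean 0 / population sd 1; minmax: [0, 1]).

    Idempotent: normalizing an already-normalized profile is a no-op up to
    floating point.
    """
    if len(profile) < 2:
        raise ValueError("need at least 2 residues to normalize")
    b = profile.values.astype(float)
    if method == "zscore":
        sd = b.std()  # population sd
        if sd == 0:
            raise ValueError("zero variance; z-score undefined")
        norm = (b - b.mean()) / sd
    elif method == "minmax":
        span = b.max() - b.min()
        if span == 0:
            raise ValueError("zero range; min-max normalization undefined")
        norm = (b - b.min()) / span
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    table = profile.table.copy()
    table["b"] = norm
    return BFactorProfile(table, label=profile.label,
                          backbone_only=profile.backbone_only, normalized=method)


@dataclass
class RegionComparison:
    region: str
    ranges: list[tuple[int, int]]
    delta: float        # mean normalized B, (a - b)
    call: str           # "a_more_mobile" | "b_more_mobile" | "no_difference"
    n_residues: int

    def as_dict(self) -> dict:
        return {"region": self.region, "ranges": self.ranges, "delta_b": self.delta,
                "call": self.call, "n_residues": self.n_residues}


def _region_mask(table: pd.DataFrame, ranges: list[tuple[int, int]]) -> np.ndarray:
    nums = table["resnum"].to_numpy()
    mask = np.zeros(len(table), dtype=bool)
    for lo, hi in ranges:
        mask |= (nums >= lo) & (nums <= hi)
    return mask


def compare_profiles(p_a: BFactorProfile, p_b: BFactorProfile,
                     regions: dict[str, list[tuple[int, int]]] | None = None,
                     threshold: float = 0.25) -> list[RegionComparison]:
    """Per-region mean difference of normalized B (a - b) with a sign call.

    A positive delta beyond ``threshold`` calls structure *a* more mobile
    in that region (equivalently: the region is better ordered in *b*).
    The call is antisymmetric under swapping the inputs. Both profiles
    should be normalized with the same method first.
    """
    regions = regions if regions is not None else DEFAULT_REGIONS
    ta = p_a.table.set_index(["chain", "resnum"])  # noqa: PD002 - local copy
    tb = p_b.table.set_index(["chain", "resnum"])
    out = []
    for name, ranges in regions.items():
        mask_a = _region_mask(p_a.table, ranges)
        mask_b = _region_mask(p_b.table, ranges)
        if not mask_a.any() or not mask_b.any():
            raise ValueError(f"region {name!r} absent from one of the profiles")
        keys_a = set(map(tuple, p_a.table.loc[mask_a, ["chain", "resnum"]].to_numpy()))
        keys_b = set(map(tuple, p_b.table.loc[mask_b, ["chain", "resnum"]].to_numpy()))
        shared = sorted(keys_a & keys_b)
        if not shared:
            raise ValueError(f"region {name!r}: no shared residues between profiles")
        da = np.array([float(ta.loc[k, "b"]) for k in shared])
        db = np.array([float(tb.loc[k, "b"]) for k in shared])
        delta = float((da - db).mean())
        if delta >= threshold:
            call = "a_more_mobile"
        elif delta <= -threshold:
            call = "b_more_mobile"
        else:
            call = "no_difference"
        out.append(RegionComparison(name, list(ranges), delta, call, len(shared)))
    return out
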