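"""File formats: TPS landmark files, long-format coordinate CSV, metadata
CSV and template definition files.

The TPS dialect supported is the common 3D one: ``LM3=<count>`` followed by
that many whitespace-separated coordinate triples, optionally closed by an
``ID=<name>`` line.  TPS has no missing-data convention, so only complete
configurations may be exported to it; partial specimens travel as CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landmarks import LandmarkConfiguration, SpecimenMeta
from .template import Template, TemplateEntry


class TPSParseError(ValueError):
    """Malformed TPS input; message names the offending line."""


def read_tps(path, template: Template | None = None
             ) -> list[LandmarkConfiguration]:
    """Read 3D landmark records (``LM3=``) from a TPS file.

    Labels are assigned from ``template`` in file order; without a template,
    generic ``p0001`` labels are used.  Raises :class:`TPSParseError` on a
    malformed count line, a point-count mismatch, or a non-numeric
    coordinate, naming the line number.
    """
    lines = Path(path).read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    n_record = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        key, _, value = line.partition("=")
        if key.strip().upper() != "LM3":
            raise TPSParseError(f"line {i + 1}: expected 'LM3=' record, "
                                f"got {line!r}")
        try:
            count = int(value)
        except ValueError:
            raise TPSParseError(f"line {i + 1}: malformed count {value!r}")
        if count < 0:
            raise TPSParseError(f"line {i + 1}: negative LM3 count")
        i += 1
        pts = []
        while i < len(lines) and len(pts) < count:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row:
                break
            fields = row.split()
            if len(fields) != 3:
                raise TPSParseError(f"line {i + 1}: expected 3 coordinates, "
                                    f"got {len(fields)}")
            try:
                pts.append([float(v) for v in fields])
            except ValueError:
                raise TPSParseError(f"line {i + 1}: non-numeric coordinate "
                                    f"in {row!r}")
            i += 1
        if len(pts) != count:
            raise TPSParseError(
                f"line {i + 1}: record declares LM3={count} but has "
                f"{len(pts)} points")
        n_record += 1
        spec_id = f"specimen_{n_record}"
        if i < len(lines):
            row = lines[i].strip()
            if row.upper().startswith("ID="):
                spec_id = row[3:].strip() or spec_id
                i += 1
        if template is not None:
            if len(template) != count:
                raise TPSParseError(
                    f"record {spec_id!r}: {count} points but template has "
                    f"{len(template)}")
            labels = template.labels
        else:
            labels = tuple(f"p{j + 1:04d}" for j in range(count))
        coords = np.asarray(pts, dtype=float).reshape(count, 3)
        configs.append(LandmarkConfiguration(
            spec_id, labels, coords, np.ones(count, dtype=bool)))
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path) -> None:
    """Write complete configurations as LM3 records with ID= lines.

    Refuses partial configurations: TPS cannot represent missing points.
    """
    out = []
    for cfg in configs:
        if not cfg.is_complete:
            raise ValueError(
                f"{cfg.specimen_id!r} has masked points; TPS has no "
                "missing-data convention — export partial data as CSV")
        out.append(f"LM3={len(cfg.labels)}")
        for xyz in cfg.coords:
            out.append(f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
        out.append(f"ID={cfg.specimen_id}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


def read_coords_csv(path, template: Template
                    ) -> list[LandmarkConfiguration]:
    """Read long-format coordinates (specimen_id,label,x,y,z).

    Labels absent for a specimen become masked points.  Unknown labels and
    duplicate (specimen, label) rows are errors.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str, "label": str})
    required = {"specimen_id", "label", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coordinate CSV missing columns {sorted(missing)}")
    unknown = set(df["label"]) - set(template.labels)
    if unknown:
        raise KeyError(f"labels not in template: {sorted(unknown)[:5]}")
    dup = df.duplicated(subset=["specimen_id", "label"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(f"duplicate row for specimen "
                         f"{row['specimen_id']!r}, label {row['label']!r}")
    configs = []
    for spec_id, grp in df.groupby("specimen_id", sort=False):
        mapping = {lab: (x, y, z) for lab, x, y, z in
                   zip(grp["label"], grp["x"], grp["y"], grp["z"])}
        configs.append(LandmarkConfiguration.from_mapping(
            str(spec_id), mapping, template))
    return configs


def write_coords_csv(configs: Iterable[LandmarkConfiguration], path) -> None:
    frames = [cfg.to_frame() for cfg in configs]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6f")


def read_meta_csv(path) -> list[SpecimenMeta]:
    df = pd.read_csv(path, dtype={"specimen_id": str})
    metas = []
    for _, row in df.iterrows():
        temp = row.get("mean_annual_temp")
        temp = None if pd.isna(temp) or temp == "" else float(temp)
        grp = row.get("climate_group")
        grp = None if pd.isna(grp) or grp == "" else str(grp)
        metas.append(SpecimenMeta(
            specimen_id=str(row["specimen_id"]), taxon=str(row["taxon"]),
            climate_group=grp, mean_annual_temp=temp,
            population=str(row.get("population", "") or "")))
    return metas


def write_meta_csv(metas: Iterable[SpecimenMeta], path) -> None:
    from .landmarks import meta_to_frame
    meta_to_frame(metas).to_csv(path, index=False)


def read_template(path) -> Template:
    """Read a template definition CSV (label,element,role,mirror_label)."""
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(TemplateEntry(
                row["label"], row["element"], row["role"],
                row["mirror_label"]))
    return Template(tuple(entries))


def write_template(template: Template, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "element", "role", "mirror_label"])
        for e in template.entries:
            writer.writerow([e.label, e.element, e.role, e.mirror_label])
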