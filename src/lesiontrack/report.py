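"""CSV reports: the per-lesion "tool card" and the response-curve table.

CSV dialect is fixed for bit-exact interop: comma-separated, UTF-8,
"." decimal, ISO-8601 dates.  Diameters and percent changes are written
to 0.1 precision; absent timepoints keep empty diameter cells.
"""

from __future__ import annotations

import csv
import datetime
from pathlib import Path

from lesiontrack.tracking import LesionTrack

CARD_COLUMNS = ["patient_id", "track_id", "study_index", "study_date", "series_label",
                "longest_mm", "perpendicular_mm", "pct_change_long", "pct_change_perp",
                "response_label"]


def _fmt(value: float | None) -> str:
    return "" if value is None else f"{value:.1f}"


def export_lesion_card(tracks: list[LesionTrack], path: str | Path,
                       study_dates: list[datetime.date] | None = None,
                       series_labels: list[str] | None = None) -> Path:
    """Write the lesion tool card: one row per (track, study).

    Rows are ordered by (patient, track, study).  Response labels come
    from ``track.response`` (empty string when not classified).
    """
    path = Path(path)
    rows = []
    for track in sorted(tracks, key=lambda t: (t.patient_id, t.track_id)):
        labels = {lab.study_index: lab.label for lab in track.response}
        for m in track.measurements:
            date = ""
            if study_dates is not None and m.study_index < len(study_dates):
                date = study_dates[m.study_index].isoformat()
            series = ""
            if series_labels is not None and m.study_index < len(series_labels):
                series = series_labels[m.study_index]
            rows.append({
                "patient_id": track.patient_id,
                "track_id": track.track_id,
                "study_index": m.study_index,
                "study_date": date,
                "series_label": series,
                "longest_mm": _fmt(m.longest_mm),
                "perpendicular_mm": _fmt(m.perpendicular_mm),
                "pct_change_long": _fmt(m.pct_change_long),
                "pct_change_perp": _fmt(m.pct_change_perp),
                "response_label": labels.get(m.study_index, ""),
            })
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CARD_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return path


def export_response_curve_table(tracks: list[LesionTrack], path: str | Path) -> Path:
    """Long-format table (track_id, study_index, longest_mm) of present
    measurements, suitable for plotting response curves."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["track_id", "study_index", "longest_mm"])
        for track in sorted(tracks, key=lambda t: t.track_id):
            for m in track.measurements:
                if m.present and m.longest_mm is not None:
                    writer.writerow([track.track_id, m.study_index, repr(float(m.longest_mm))])
    return path
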