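"""Reading and writing keystroke event data.

Two on-disk representations are supported:

* **Standard MIDI files** (format 0 or 1).  Tap onsets are note-on events
  with velocity > 0; note-offs and zero-velocity note-ons (the running-status
  off convention) are discarded.  Tick times are converted to milliseconds
  using the file's division and tempo map.  A small self-contained SMF
  parser/writer is included; only PPQ (ticks-per-quarter) division is
  supported, not SMPTE.

* **A plain tabular fixture format**: a UTF-8 tab-delimited table with one
  row per keystroke and columns for every :class:`~turntap.types.TrialMeta`
  and :class:`~turntap.types.TapEvent` field.  This is the lossless
  round-trip format used by the synthetic-data generator and the analysis
  drivers.
"""

from __future__ import annotations

import struct
from pathlib import Path

import pandas as pd

from turntap.types import EVENT_FIELDS, META_FIELDS, TapEvent, Trial, TrialMeta

FIXTURE_COLUMNS = META_FIELDS + EVENT_FIELDS

# ---------------------------------------------------------------------------
# Standard MIDI
# ---------------------------------------------------------------------------

_DEFAULT_TEMPO_US = 500_000  # microseconds per quarter note (120 BPM)


def _read_varint(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _write_varint(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _parse_track(data: bytes) -> list[tuple[int, int, int, int, int]]:
    """Walk one MTrk chunk.

    Returns raw events as (abs_tick, status, channel0, data1, data2) for
    channel messages and (abs_tick, 0xFF, meta_type, -1, tempo_or_0) for
    tempo meta events.  Channel is 0-based on the wire.
    """
    events = []
    pos = 0
    tick = 0
    running_status = None
    while pos < len(data):
        delta, pos = _read_varint(data, pos)
        tick += delta
        status = data[pos]
        if status & 0x80:
            pos += 1
            if status < 0xF0:
                running_status = status
        else:
            if running_status is None:
                raise ValueError("MIDI running status byte before any status")
            status = running_status
        if status == 0xFF:  # meta
            meta_type = data[pos]
            pos += 1
            length, pos = _read_varint(data, pos)
            payload = data[pos:pos + length]
            pos += length
            if meta_type == 0x51:  # set tempo
                tempo = int.from_bytes(payload, "big")
                events.append((tick, 0xFF, 0x51, -1, tempo))
            if meta_type == 0x2F:  # end of track
                break
        elif status in (0xF0, 0xF7):  # sysex
            length, pos = _read_varint(data, pos)
            pos += length
        else:
            kind = status & 0xF0
            channel = status & 0x0F
            if kind in (0xC0, 0xD0):  # program change / channel pressure: 1 data byte
                d1 = data[pos]
                pos += 1
                events.append((tick, kind, channel, d1, 0))
            else:
                d1, d2 = data[pos], data[pos + 1]
                pos += 2
                events.append((tick, kind, channel, d1, d2))
    return events


def _tick_to_ms(tick: int, tempo_map: list[tuple[int, int]], ppq: int) -> float:
    """Convert an absolute tick to milliseconds via a sorted tempo map
    [(tick, tempo_us), ...] with an entry at tick 0."""
    ms = 0.0
    for (t0, tempo), (t1, _next) in zip(tempo_map, tempo_map[1:] + [(tick, 0)]):
        if t0 >= tick:
            break
        span = min(t1, tick) - t0
        ms += span * tempo / ppq / 1000.0
    return ms


def read_midi_events(path: str | Path, channel_map: dict[int, str]) -> list[TapEvent]:
    """Extract tap onsets from a standard MIDI file.

    ``channel_map`` assigns 1-based MIDI channels to performer labels, e.g.
    ``{1: "A", 2: "B"}``.  A note-on on an unmapped channel is an error.
    Times are trial-relative milliseconds (offset so the stream starts where
    the file's tick origin does).
    """
    data = Path(path).read_bytes()
    if len(data) < 14 or data[:4] != b"MThd":
        raise ValueError(f"{path}: not a standard MIDI file")
    hlen, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise ValueError(f"{path}: SMPTE division not supported")
    ppq = division
    pos = 8 + hlen
    raw: list[tuple[int, int, int, int, int]] = []
    for _ in range(ntrks):
        if data[pos:pos + 4] != b"MTrk":
            raise ValueError(f"{path}: expected MTrk chunk at byte {pos}")
        tlen = struct.unpack(">I", data[pos + 4:pos + 8])[0]
        raw.extend(_parse_track(data[pos + 8:pos + 8 + tlen]))
        pos += 8 + tlen

    tempo_map = sorted([(t, v) for t, s, mt, _, v in raw if s == 0xFF and mt == 0x51])
    if not tempo_map or tempo_map[0][0] > 0:
        tempo_map.insert(0, (0, _DEFAULT_TEMPO_US))

    events: list[TapEvent] = []
    for tick, status, channel0, d1, d2 in sorted(raw, key=lambda e: e[0]):
        if status != 0x90 or d2 == 0:  # keep only genuine note-ons
            continue
        channel = channel0 + 1
        if channel not in channel_map:
            raise ValueError(f"{path}: note-on on unmapped MIDI channel {channel}")
        events.append(TapEvent(
            time_ms=_tick_to_ms(tick, tempo_map, ppq),
            pitch=d1, velocity=d2, performer=channel_map[channel],
        ))
    if not events:
        raise ValueError(f"{path}: no note-on events found")
    return events


def write_midi(events: list[TapEvent], path: str | Path,
               performer_channels: dict[str, int] | None = None,
               ppq: int = 500) -> None:
    """Write tap events as a format-0 standard MIDI file.

    With the default PPQ of 500 and the fixed 500 000 us/quarter tempo one
    tick equals exactly one millisecond, so integer-millisecond onsets
    round-trip without loss.  Each tap gets a note-off 100 ms later (or at
    the next event, whichever is sooner) purely for well-formedness.
    """
    performer_channels = performer_channels or {"A": 1, "B": 2}
    tempo = _DEFAULT_TEMPO_US
    msgs: list[tuple[int, bytes]] = [(0, bytes([0xFF, 0x51, 0x03]) + tempo.to_bytes(3, "big"))]
    for ev in sorted(events, key=lambda e: e.time_ms):
        ch0 = performer_channels[ev.performer] - 1
        on_tick = round(ev.time_ms * ppq * 1000 / tempo)
        msgs.append((on_tick, bytes([0x90 | ch0, ev.pitch, ev.velocity])))
        msgs.append((on_tick + round(100 * ppq * 1000 / tempo),
                     bytes([0x80 | ch0, ev.pitch, 0])))
    msgs.sort(key=lambda m: m[0])
    track = bytearray()
    prev = 0
    for tick, payload in msgs:
        track += _write_varint(tick - prev) + payload
        prev = tick
    track += _write_varint(0) + bytes([0xFF, 0x2F, 0x00])
    out = bytearray(b"MThd" + struct.pack(">IHHH", 6, 0, 1, ppq))
    out += b"MTrk" + struct.pack(">I", len(track)) + track
    Path(path).write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# Tabular fixture format
# ---------------------------------------------------------------------------

def write_fixture(dataset: list[Trial], path: str | Path) -> None:
    """Write a dataset as a tab-delimited table, one row per keystroke.

    Column order is deterministic (metadata fields then event fields) and
    the format is lossless for all fields.  An empty dataset produces a
    header-only file.
    """
    rows = []
    for trial in dataset:
        meta = {f: getattr(trial.meta, f) for f in META_FIELDS}
        for ev in trial.events:
            row = dict(meta)
            row.update({f: getattr(ev, f) for f in EVENT_FIELDS})
            rows.append(row)
    df = pd.DataFrame(rows, columns=FIXTURE_COLUMNS)
    # repr() is the shortest decimal string that round-trips a float exactly;
    # pandas' default float formatter can drop the final digit
    df["time_ms"] = [repr(float(v)) for v in df["time_ms"]] if len(df) else df["time_ms"]
    df.to_csv(path, sep="\t", index=False)


def read_fixture(path: str | Path) -> list[Trial]:
    """Read a fixture table back into a list of trials.

    Rows are grouped by trial identity; every trial is validated against the
    type invariants (sorted times, legal labels).  Missing columns, unsorted
    times, or unknown task labels raise descriptive errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "subject_id": str},
                     float_precision="round_trip")
    missing = [c for c in FIXTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing fixture columns {missing}")
    trials: list[Trial] = []
    if df.empty:
        return trials
    key_cols = ["pair_id", "subject_id", "task", "block", "trial_index"]
    for _, grp in df.groupby(key_cols, sort=True, dropna=False):
        first = grp.iloc[0]
        subject = first["subject_id"]
        meta = TrialMeta(
            pair_id=str(first["pair_id"]),
            subject_id=None if pd.isna(subject) else str(subject),
            task=str(first["task"]),
            block=int(first["block"]),
            trial_index=int(first["trial_index"]),
            predictability=str(first["predictability"]),
            turn_pattern=str(first["turn_pattern"]),
            starting_performer=str(first["starting_performer"]),
            flagged_online=bool(first["flagged_online"]),
        )
        events = [
            TapEvent(time_ms=float(r.time_ms), pitch=int(r.pitch),
                     velocity=int(r.velocity), performer=str(r.performer))
            for r in grp.itertuples()
        ]
        trial = Trial(meta=meta, events=events)
        trial.validate()
        trials.append(trial)
    return trials
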