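"""Minimal Standard MIDI File (format 0) writer and reader.

Covers exactly what the feedback engine emits: one track at a fixed
tempo, note-on/note-off pairs, and text meta events for cue markers
(white-noise rest cue, mid-block beep).  Times are quantized to ticks
(480 per quarter note at the configured tempo), so a write/read round
trip is exact at tick resolution.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

__all__ = ["MidiNote", "MidiText", "write_smf", "read_smf", "seconds_to_ticks", "ticks_to_seconds"]

TICKS_PER_QUARTER = 480
DEFAULT_TEMPO_US = 500_000  # microseconds per quarter note (120 BPM)

_META_TEXT = 0x01
_META_TEMPO = 0x51
_META_EOT = 0x2F


class MidiError(ValueError):
    """Raised on malformed SMF data or unencodable events."""


@dataclass(frozen=True)
class MidiNote:
    """One note at absolute tick time."""

    onset_ticks: int
    duration_ticks: int
    pitch: int
    velocity: int
    channel: int = 0


@dataclass(frozen=True)
class MidiText:
    """One text meta event (cue marker) at absolute tick time."""

    onset_ticks: int
    text: str


def seconds_to_ticks(seconds: float, tempo_us: int = DEFAULT_TEMPO_US) -> int:
    return int(round(seconds * 1e6 / tempo_us * TICKS_PER_QUARTER))


def ticks_to_seconds(ticks: int, tempo_us: int = DEFAULT_TEMPO_US) -> float:
    return ticks * tempo_us / 1e6 / TICKS_PER_QUARTER


def _vlq(value: int) -> bytes:
    """Encode a non-negative integer as a MIDI variable-length quantity."""
    if value < 0:
        raise MidiError(f"cannot encode negative delta time {value}")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(chunks))


def write_smf(
    notes: list[MidiNote],
    texts: list[MidiText],
    path,
    tempo_us: int = DEFAULT_TEMPO_US,
) -> None:
    """Write a single-track (format 0) SMF with the given notes and text
    markers.  Events need not be pre-sorted; simultaneous events are
    ordered meta < note-off < note-on for a clean round trip."""
    for n in notes:
        if not (0 <= n.pitch <= 127 and 1 <= n.velocity <= 127):
            raise MidiError(f"pitch/velocity out of MIDI range: {n}")
        if n.duration_ticks <= 0:
            raise MidiError(f"note duration must be positive ticks: {n}")

    # (tick, order, payload) — order keys: 0 meta, 1 note-off, 2 note-on
    events: list[tuple[int, int, bytes]] = [
        (0, 0, bytes([0xFF, _META_TEMPO, 0x03]) + tempo_us.to_bytes(3, "big"))
    ]
    for t in texts:
        data = t.text.encode("utf-8")
        if len(data) > 127:
            raise MidiError("text marker longer than 127 bytes")
        events.append((t.onset_ticks, 0, bytes([0xFF, _META_TEXT, len(data)]) + data))
    for n in notes:
        on = bytes([0x90 | n.channel, n.pitch, n.velocity])
        off = bytes([0x80 | n.channel, n.pitch, 0])
        events.append((n.onset_ticks, 2, on))
        events.append((n.onset_ticks + n.duration_ticks, 1, off))
    events.sort(key=lambda e: (e[0], e[1]))

    track = bytearray()
    prev_tick = 0
    for tick, _, payload in events:
        track += _vlq(tick - prev_tick)
        track += payload
        prev_tick = tick
    track += _vlq(0) + bytes([0xFF, _META_EOT, 0x00])

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, TICKS_PER_QUARTER))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))


def _read_vlq(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def read_smf(path) -> tuple[list[MidiNote], list[MidiText], int]:
    """Read an SMF written by :func:`write_smf` (or any simple format-0/1
    single-tempo file).  Returns (notes, texts, tempo_us); note-offs are
    matched to the earliest open note-on of the same pitch/channel."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise MidiError("not a Standard MIDI File (missing MThd)")
    hdr_len, fmt, n_tracks, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise MidiError("SMPTE time division not supported")
    pos = 8 + hdr_len
    if data[pos : pos + 4] != b"MTrk":
        raise MidiError("missing MTrk chunk")
    (track_len,) = struct.unpack(">I", data[pos + 4 : pos + 8])
    track = data[pos + 8 : pos + 8 + track_len]

    tempo_us = DEFAULT_TEMPO_US
    notes: list[MidiNote] = []
    texts: list[MidiText] = []
    open_notes: dict[tuple[int, int], list[tuple[int, int]]] = {}
    tick = 0
    p = 0
    status = 0
    while p < len(track):
        delta, p = _read_vlq(track, p)
        tick += delta
        byte = track[p]
        if byte >= 0x80:
            status = byte
            p += 1
        if status == 0xFF:
            meta_type = track[p]
            length, p2 = _read_vlq(track, p + 1)
            payload = track[p2 : p2 + length]
            p = p2 + length
            if meta_type == _META_TEMPO:
                tempo_us = int.from_bytes(payload, "big")
            elif meta_type == _META_TEXT:
                texts.append(MidiText(tick, payload.decode("utf-8")))
            elif meta_type == _META_EOT:
                break
            continue
        kind = status & 0xF0
        channel = status & 0x0F
        if kind in (0x90, 0x80):
            pitch, velocity = track[p], track[p + 1]
            p += 2
            key = (channel, pitch)
            if kind == 0x90 and velocity > 0:
                open_notes.setdefault(key, []).append((tick, velocity))
            else:  # note-off, or note-on with velocity 0
                if open_notes.get(key):
                    onset, vel = open_notes[key].pop(0)
                    notes.append(MidiNote(onset, tick - onset, pitch, vel, channel))
        elif kind in (0xA0, 0xB0, 0xE0):
            p += 2
        elif kind in (0xC0, 0xD0):
            p += 1
        else:
            raise MidiError(f"unsupported status byte 0x{status:02x}")
    notes.sort(key=lambda n: (n.onset_ticks, n.pitch))
    texts.sort(key=lambda t: t.onset_ticks)
    return notes, texts, tempo_us
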