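"""Minimal EDF / BDF (Biosemi 24-bit) codec for continuous multichannel data.

Supports exactly what the pipeline needs: uncompressed continuous recordings,
one-second data records, identical sampling rate on every channel. Digital
ranges are the full 16-bit (EDF) or 24-bit (BDF) span; physical ranges are
taken per channel from the data, so a write/read round trip is exact up to
one quantization step.
"""

from __future__ import annotations

import numpy as np

_EDF_DIG = (-32768, 32767)
_BDF_DIG = (-8388608, 8388607)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _num(value: float, width: int) -> bytes:
    if float(value).is_integer() and len(str(int(value))) <= width:
        return _pad(str(int(value)), width)
    for fmt in (f"{value:.{width - 2}g}", f"{value:.0f}"):
        s = fmt[:width]
        try:
            float(s)
            return _pad(s, width)
        except ValueError:
            continue
    raise ValueError(f"cannot encode {value} in {width} ascii bytes")


def write(path, data: np.ndarray, rate: float, labels: list[str], *,
          bdf: bool = False) -> None:
    """Write a channels x samples float array as EDF (16-bit) or BDF (24-bit).

    Trailing samples that do not fill a whole 1-s record are dropped.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] != len(labels):
        raise ValueError("data must be channels x samples matching labels")
    if rate <= 0 or rate != int(rate):
        raise ValueError("EDF writer requires a positive integer rate")
    spr = int(rate)  # samples per 1-s record
    n_rec = data.shape[1] // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one data record (1 s)")
    n_ch = len(labels)
    dig_min, dig_max = _BDF_DIG if bdf else _EDF_DIG

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    with open(path, "wb") as f:
        if bdf:
            f.write(b"\xffBIOSEMI")
        else:
            f.write(_pad("0", 8))
        f.write(_pad("", 80))                     # patient id
        f.write(_pad("", 80))                     # recording id
        f.write(_pad("01.01.00", 8))              # start date
        f.write(_pad("00.00.00", 8))              # start time
        f.write(_num(256 * (1 + n_ch), 8))        # header length
        f.write(_pad("24BIT" if bdf else "", 44))
        f.write(_num(n_rec, 8))
        f.write(_num(1, 8))                       # record duration (s)
        f.write(_num(n_ch, 4))
        for lab in labels:
            f.write(_pad(lab, 16))
        f.write(_pad("", 80) * n_ch)              # transducer
        f.write(_pad("uV", 8) * n_ch)
        for v in phys_min:
            f.write(_num(v, 8))
        for v in phys_max:
            f.write(_num(v, 8))
        f.write(_num(dig_min, 8) * n_ch)
        f.write(_num(dig_max, 8) * n_ch)
        f.write(_pad("", 80) * n_ch)              # prefiltering
        f.write(_num(spr, 8) * n_ch)
        f.write(_pad("", 32) * n_ch)

        # re-read physical bounds exactly as the ascii header stores them so
        # that encode/decode use the same gain
        pmin = np.array([float(_num(v, 8)) for v in phys_min])
        pmax = np.array([float(_num(v, 8)) for v in phys_max])
        gain = (dig_max - dig_min) / (pmax - pmin)
        for r in range(n_rec):
            chunk = data[:, r * spr:(r + 1) * spr]
            dig = np.rint((chunk - pmin[:, None]) * gain[:, None] + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype(np.int64)
            if bdf:
                le = dig.astype("<i4").view(np.uint8).reshape(n_ch, spr, 4)
                f.write(le[:, :, :3].tobytes())
            else:
                f.write(dig.astype("<i2").tobytes())


def read(path):
    """Read an EDF or BDF file; returns (data, rate, labels)."""
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise ValueError("truncated EDF/BDF header")
        magic = head[:8]
        if magic == b"\xffBIOSEMI":
            bdf = True
        elif magic.strip() == b"0":
            bdf = False
        else:
            raise ValueError("not an EDF or BDF file")
        try:
            n_rec = int(head[236:244].decode("ascii").strip())
            dur = float(head[244:252].decode("ascii").strip())
            n_ch = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError("unreadable EDF/BDF header") from exc
        sig = f.read(256 * n_ch)
        if len(sig) < 256 * n_ch or n_ch <= 0 or n_rec <= 0 or dur <= 0:
            raise ValueError("unreadable EDF/BDF header")

        def field(offset, width):
            base = offset * n_ch
            return [sig[base + i * width: base + (i + 1) * width]
                    for i in range(n_ch)]

        labels = [b.decode("ascii").strip() for b in field(0, 16)]
        pmin = np.array([float(b) for b in field(16 + 80 + 8, 8)])
        pmax = np.array([float(b) for b in field(16 + 80 + 16, 8)])
        dmin = np.array([float(b) for b in field(16 + 80 + 24, 8)])
        dmax = np.array([float(b) for b in field(16 + 80 + 32, 8)])
        spr = np.array([int(b) for b in field(16 + 80 + 40 + 80, 8)])
        if len(set(spr)) != 1:
            raise ValueError("channels with differing rates are unsupported")
        spr = int(spr[0])
        rate = spr / dur

        bps = 3 if bdf else 2
        payload = f.read(n_rec * n_ch * spr * bps)
        if len(payload) < n_rec * n_ch * spr * bps:
            raise ValueError("truncated EDF/BDF data section")
        raw = np.frombuffer(payload, dtype=np.uint8)
        raw = raw.reshape(n_rec, n_ch, spr, bps)
        if bdf:
            dig = (raw[..., 0].astype(np.int32)
                   | (raw[..., 1].astype(np.int32) << 8)
                   | (raw[..., 2].astype(np.int32) << 16))
            dig = np.where(dig >= 1 << 23, dig - (1 << 24), dig)
        else:
            dig = raw.copy().view("<i2")[..., 0].astype(np.int32)
        dig = np.transpose(dig, (1, 0, 2)).reshape(n_ch, n_rec * spr)
        gain = (pmax - pmin) / (dmax - dmin)
        data = (dig - dmin[:, None]) * gain[:, None] + pmin[:, None]
    return data, rate, labels
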