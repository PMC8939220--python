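"""Bit-exact container format for all query structures.

Layout: a fixed header (magic ``KCSF``, format version, scheme tag,
section count), a little-endian fixed-width section table (name, offset,
length, CRC32), then the section payloads.  Every structure loads back
to answer queries identically; corruption is caught by per-section
checksums rather than surfacing as silently wrong counts.

Sections follow the component structure (Bloom filter, CSF, cascade
layers, residual/corrections), which is what makes per-component size
breakdowns possible without deserializing payloads.
"""

from __future__ import annotations

import struct
import zlib
from pathlib import Path

import numpy as np

from .bcsf import BCSFStructure
from .bloom_filter import BloomFilter
from .csf_core import CSFStructure, _Chunk
from .layered_schemes import AMBStructure, FILStructure, _Layer
from .minimizers import MinimizerScheme
from .prefix_code import PrefixCode

__all__ = [
    "save",
    "load",
    "dumps",
    "loads",
    "inspect",
    "SerializationError",
    "MagicError",
    "VersionError",
    "ChecksumError",
    "TruncatedError",
]

MAGIC = b"KCSF"
VERSION = 1
_HEADER = struct.Struct("<4sHBH")  # magic, version, scheme tag, n sections
_SECTION = struct.Struct("<12sQQI")  # name, offset, length, crc32

_TAGS = {"csf": 0, "bcsf": 1, "amb": 2, "fil": 3}
_TAG_NAMES = {v: k for k, v in _TAGS.items()}


class SerializationError(Exception):
    """Base class for container format errors."""


class MagicError(SerializationError):
    pass


class VersionError(SerializationError):
    pass


class ChecksumError(SerializationError):
    pass


class TruncatedError(SerializationError):
    pass


# ---------------------------------------------------------------------------
# primitive encoders
# ---------------------------------------------------------------------------

def _enc_u64_array(a: np.ndarray) -> bytes:
    a = np.ascontiguousarray(a, dtype="<u8")
    return struct.pack("<Q", a.size) + a.tobytes()


def _dec_u64_array(buf: memoryview, off: int) -> tuple[np.ndarray, int]:
    (n,) = struct.unpack_from("<Q", buf, off)
    off += 8
    a = np.frombuffer(buf, dtype="<u8", count=n, offset=off).astype(np.uint64)
    return a, off + 8 * n


def _enc_code(code: PrefixCode) -> bytes:
    syms = np.asarray(code.symbols, dtype="<i8")
    lens = np.asarray(code.lengths, dtype="<u1")
    return (
        struct.pack("<QB", syms.size, code.max_len) + syms.tobytes() + lens.tobytes()
    )


def _dec_code(buf: memoryview, off: int) -> tuple[PrefixCode, int]:
    n, max_len = struct.unpack_from("<QB", buf, off)
    off += 9
    syms = np.frombuffer(buf, dtype="<i8", count=n, offset=off)
    off += 8 * n
    lens = np.frombuffer(buf, dtype="<u1", count=n, offset=off)
    off += n
    return (
        PrefixCode(
            symbols=[int(s) for s in syms],
            lengths=[int(l) for l in lens],
            max_len=int(max_len),
        ),
        off,
    )


def _enc_csf(csf: CSFStructure) -> bytes:
    parts = [
        _enc_code(csf.code),
        struct.pack("<dQQBQ", csf.gamma, csf.seed, csf.num_keys, csf.wlen, len(csf.chunks)),
    ]
    for ch in csf.chunks:
        parts.append(struct.pack("<BQ", ch.attempt, ch.seg_len))
        parts.append(np.ascontiguousarray(ch.words, dtype="<u8").tobytes())
    return b"".join(parts)


def _dec_csf(buf: memoryview, off: int) -> tuple[CSFStructure, int]:
    from ._hash import mix_seeds

    code, off = _dec_code(buf, off)
    gamma, seed, num_keys, wlen, n_chunks = struct.unpack_from("<dQQBQ", buf, off)
    off += 33
    chunks = []
    for c in range(n_chunks):
        attempt, seg_len = struct.unpack_from("<BQ", buf, off)
        off += 9
        n_words = (3 * seg_len + 63) // 64
        words = np.frombuffer(buf, dtype="<u8", count=n_words, offset=off).astype(np.uint64)
        off += 8 * n_words
        chunks.append(
            _Chunk(seed=mix_seeds(seed, c, attempt), seg_len=seg_len, words=words, attempt=attempt)
        )
    return (
        CSFStructure(
            code=code, gamma=gamma, seed=seed, num_keys=num_keys, wlen=wlen, chunks=chunks
        ),
        off,
    )


def _enc_bloom(bf: BloomFilter) -> bytes:
    return (
        struct.pack("<QBdQQ", bf.m_bits, bf.num_hashes, bf.target_fp, bf.seed, bf.n_inserted)
        + np.ascontiguousarray(bf.words, dtype="<u8").tobytes()
    )


def _dec_bloom(buf: memoryview, off: int) -> tuple[BloomFilter, int]:
    m_bits, num_hashes, target_fp, seed, n_inserted = struct.unpack_from("<QBdQQ", buf, off)
    off += 33
    n_words = (m_bits + 63) // 64
    words = np.frombuffer(buf, dtype="<u8", count=n_words, offset=off).astype(np.uint64)
    off += 8 * n_words
    return (
        BloomFilter(
            m_bits=m_bits,
            num_hashes=num_hashes,
            target_fp=target_fp,
            seed=seed,
            n_inserted=n_inserted,
            words=words,
        ),
        off,
    )


def _enc_bcsf(b: BCSFStructure) -> bytes:
    flags = (1 if b.bloom is not None else 0) | (2 if b.csf is not None else 0)
    eps = b.epsilon if b.epsilon is not None else float("nan")
    parts = [struct.pack("<BqQd", flags, b.dominant_value, b.num_keys, eps)]
    if b.bloom is not None:
        blob = _enc_bloom(b.bloom)
        parts.append(struct.pack("<Q", len(blob)))
        parts.append(blob)
    if b.csf is not None:
        blob = _enc_csf(b.csf)
        parts.append(struct.pack("<Q", len(blob)))
        parts.append(blob)
    return b"".join(parts)


def _dec_bcsf(buf: memoryview, off: int) -> tuple[BCSFStructure, int]:
    flags, dominant, num_keys, eps = struct.unpack_from("<BqQd", buf, off)
    off += 25
    bloom = csf = None
    if flags & 1:
        (_,) = struct.unpack_from("<Q", buf, off)
        off += 8
        bloom, off = _dec_bloom(buf, off)
    if flags & 2:
        (_,) = struct.unpack_from("<Q", buf, off)
        off += 8
        csf, off = _dec_csf(buf, off)
    return (
        BCSFStructure(
            dominant_value=dominant,
            num_keys=num_keys,
            epsilon=None if eps != eps else eps,
            bloom=bloom,
            csf=csf,
        ),
        off,
    )


# ---------------------------------------------------------------------------
# per-scheme section assembly
# ---------------------------------------------------------------------------

def _sections_csf(s: CSFStructure) -> list[tuple[str, bytes]]:
    return [("csf", _enc_csf(s))]


def _sections_bcsf(s: BCSFStructure) -> list[tuple[str, bytes]]:
    eps = s.epsilon if s.epsilon is not None else float("nan")
    meta = struct.pack("<qQd", s.dominant_value, s.num_keys, eps)
    out = [("meta", meta)]
    out.append(("bloom", _enc_bloom(s.bloom) if s.bloom is not None else b""))
    out.append(("csf", _enc_csf(s.csf) if s.csf is not None else b""))
    return out


def _sections_amb(s: AMBStructure) -> list[tuple[str, bytes]]:
    meta = struct.pack("<BQQB", s.k, s.delta, s.num_keys, len(s.layers))
    for layer in s.layers:
        meta += struct.pack("<BQ", layer.scheme.m, layer.scheme.order_seed)
    out = [("meta", meta)]
    for i, layer in enumerate(s.layers):
        out.append((f"layer{i}", _enc_bcsf(layer.table)))
    out.append(("residual", _enc_bcsf(s.residual) if s.residual is not None else b""))
    return out


def _sections_fil(s: FILStructure) -> list[tuple[str, bytes]]:
    meta = struct.pack("<BQB", s.k, s.num_keys, len(s.layers))
    for layer in s.layers:
        meta += struct.pack("<BQ", layer.scheme.m, layer.scheme.order_seed)
    out = [("meta", meta)]
    for i, layer in enumerate(s.layers):
        out.append((f"layer{i}", _enc_bcsf(layer.table)))
    out.append(("corr", _enc_bcsf(s.corrections)))
    return out


def _assemble_csf(sections: dict[str, bytes]) -> CSFStructure:
    s, _ = _dec_csf(memoryview(sections["csf"]), 0)
    return s


def _assemble_bcsf(sections: dict[str, bytes]) -> BCSFStructure:
    dominant, num_keys, eps = struct.unpack_from("<qQd", sections["meta"], 0)
    bloom = _dec_bloom(memoryview(sections["bloom"]), 0)[0] if sections["bloom"] else None
    csf = _dec_csf(memoryview(sections["csf"]), 0)[0] if sections["csf"] else None
    return BCSFStructure(
        dominant_value=dominant,
        num_keys=num_keys,
        epsilon=None if eps != eps else eps,
        bloom=bloom,
        csf=csf,
    )


def _assemble_amb(sections: dict[str, bytes]) -> AMBStructure:
    meta = sections["meta"]
    k, delta, num_keys, n_layers = struct.unpack_from("<BQQB", meta, 0)
    off = 18
    layers = []
    for i in range(n_layers):
        m, order_seed = struct.unpack_from("<BQ", meta, off)
        off += 9
        table = _dec_bcsf(memoryview(sections[f"layer{i}"]), 0)[0]
        layers.append(_Layer(scheme=MinimizerScheme(m, order_seed), table=table))
    residual = (
        _dec_bcsf(memoryview(sections["residual"]), 0)[0] if sections["residual"] else None
    )
    return AMBStructure(
        k=k, delta=delta, layers=layers, residual=residual, num_keys=num_keys
    )


def _assemble_fil(sections: dict[str, bytes]) -> FILStructure:
    meta = sections["meta"]
    k, num_keys, n_layers = struct.unpack_from("<BQB", meta, 0)
    off = 10
    layers = []
    for i in range(n_layers):
        m, order_seed = struct.unpack_from("<BQ", meta, off)
        off += 9
        table = _dec_bcsf(memoryview(sections[f"layer{i}"]), 0)[0]
        layers.append(_Layer(scheme=MinimizerScheme(m, order_seed), table=table))
    corrections = _dec_bcsf(memoryview(sections["corr"]), 0)[0]
    return FILStructure(k=k, layers=layers, corrections=corrections, num_keys=num_keys)


def _scheme_of(structure) -> str:
    if isinstance(structure, CSFStructure):
        return "csf"
    if isinstance(structure, BCSFStructure):
        return "bcsf"
    if isinstance(structure, AMBStructure):
        return "amb"
    if isinstance(structure, FILStructure):
        return "fil"
    raise TypeError(f"cannot serialize {type(structure).__name__}")


_SECTIONERS = {
    "csf": _sections_csf,
    "bcsf": _sections_bcsf,
    "amb": _sections_amb,
    "fil": _sections_fil,
}
_ASSEMBLERS = {
    "csf": _assemble_csf,
    "bcsf": _assemble_bcsf,
    "amb": _assemble_amb,
    "fil": _assemble_fil,
}


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

def dumps(structure) -> bytes:
    scheme = _scheme_of(structure)
    sections = _SECTIONERS[scheme](structure)
    header = _HEADER.pack(MAGIC, VERSION, _TAGS[scheme], len(sections))
    table = b""
    payload = b""
    for name, blob in sections:
        table += _SECTION.pack(
            name.encode().ljust(12, b"\0"), len(payload), len(blob), zlib.crc32(blob)
        )
        payload += blob
    return header + table + payload


def loads(data: bytes):
    scheme, sections = _parse(data)
    return _ASSEMBLERS[scheme](sections)


def _parse(data: bytes) -> tuple[str, dict[str, bytes]]:
    if len(data) < _HEADER.size:
        raise TruncatedError("container shorter than its header")
    magic, version, tag, n_sections = _HEADER.unpack_from(data, 0)
    if magic != MAGIC:
        raise MagicError(f"bad magic {magic!r}")
    if version != VERSION:
        raise VersionError(f"unsupported format version {version}")
    if tag not in _TAG_NAMES:
        raise SerializationError(f"unknown scheme tag {tag}")
    table_end = _HEADER.size + n_sections * _SECTION.size
    if len(data) < table_end:
        raise TruncatedError("container shorter than its section table")
    sections: dict[str, bytes] = {}
    for i in range(n_sections):
        raw_name, offset, length, crc = _SECTION.unpack_from(
            data, _HEADER.size + i * _SECTION.size
        )
        name = raw_name.rstrip(b"\0").decode()
        start = table_end + offset
        if start + length > len(data):
            raise TruncatedError(f"section {name!r} extends past end of file")
        blob = data[start : start + length]
        if zlib.crc32(blob) != crc:
            raise ChecksumError(f"section {name!r} failed its CRC check")
        sections[name] = blob
    return _TAG_NAMES[tag], sections


def save(structure, path: str | Path) -> None:
    Path(path).write_bytes(dumps(structure))


def load(path: str | Path):
    return loads(Path(path).read_bytes())


def inspect(data_or_path) -> dict:
    """Header and per-section sizes without assembling the structure."""
    if isinstance(data_or_path, (str, Path)):
        data = Path(data_or_path).read_bytes()
    else:
        data = data_or_path
    scheme, sections = _parse(data)
    header_bytes = _HEADER.size + len(sections) * _SECTION.size
    return {
        "scheme": scheme,
        "header_bytes": header_bytes,
        "sections": {name: len(blob) for name, blob in sections.items()},
        "total_bytes": len(data),
    }
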