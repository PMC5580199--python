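"""AES block cipher (128/256-bit keys) with CTR and CBC modes.

Implemented from the standard specification; the S-box and GF(2^8)
multiplication tables are derived programmatically (multiplicative inverse
modulo x^8+x^4+x^3+x+1 plus the affine map) rather than transcribed, and the
whole cipher is validated against the standard known-answer vectors in the
test suite.  Block transforms are vectorized with numpy across blocks, so
CTR mode and CBC decryption run in bulk; CBC encryption chains and is
necessarily sequential.

This module provides raw primitives only; authenticated-envelope
construction (key wrapping, MACs, digests) lives in
:mod:`asthmawatch.envelope`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AES", "pkcs7_pad", "pkcs7_unpad"]

_POLY = 0x11B


def _gf_mul(a: int, b: int) -> int:
    out = 0
    while b:
        if b & 1:
            out ^= a
        a <<= 1
        if a & 0x100:
            a ^= _POLY
        b >>= 1
    return out


def _build_tables():
    # multiplicative inverses in GF(2^8)
    inv = [0] * 256
    for a in range(1, 256):
        for b in range(1, 256):
            if _gf_mul(a, b) == 1:
                inv[a] = b
                break
    sbox = np.zeros(256, dtype=np.uint8)
    for a in range(256):
        x = inv[a]
        s = 0x63
        for shift in range(5):
            s ^= ((x << shift) | (x >> (8 - shift))) & 0xFF
        sbox[a] = s
    inv_sbox = np.zeros(256, dtype=np.uint8)
    inv_sbox[sbox] = np.arange(256, dtype=np.uint8)
    muls = {
        m: np.array([_gf_mul(m, a) for a in range(256)], dtype=np.uint8)
        for m in (2, 3, 9, 11, 13, 14)
    }
    return sbox, inv_sbox, muls


_SBOX, _INV_SBOX, _MUL = _build_tables()

# ShiftRows permutations on the column-major flat block layout
_SHIFT = np.array([4 * ((c + r) % 4) + r for c in range(4) for r in range(4)])
_INV_SHIFT = np.array([4 * ((c - r) % 4) + r for c in range(4) for r in range(4)])

_RCON = [0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36, 0x6C, 0xD8]


def _expand_key(key: bytes) -> np.ndarray:
    nk = len(key) // 4
    nr = {4: 10, 8: 14}[nk]
    words = [list(key[4 * i : 4 * i + 4]) for i in range(nk)]
    for i in range(nk, 4 * (nr + 1)):
        temp = list(words[i - 1])
        if i % nk == 0:
            temp = temp[1:] + temp[:1]
            temp = [int(_SBOX[b]) for b in temp]
            temp[0] ^= _RCON[i // nk - 1]
        elif nk > 6 and i % nk == 4:
            temp = [int(_SBOX[b]) for b in temp]
        words.append([a ^ b for a, b in zip(words[i - nk], temp)])
    flat = np.array(words, dtype=np.uint8).reshape(nr + 1, 16)
    return flat


def _mix_columns(state: np.ndarray, inverse: bool = False) -> np.ndarray:
    a = state.reshape(-1, 4, 4)
    a0, a1, a2, a3 = a[:, :, 0], a[:, :, 1], a[:, :, 2], a[:, :, 3]
    if not inverse:
        m2, m3 = _MUL[2], _MUL[3]
        b = np.stack(
            [
                m2[a0] ^ m3[a1] ^ a2 ^ a3,
                a0 ^ m2[a1] ^ m3[a2] ^ a3,
                a0 ^ a1 ^ m2[a2] ^ m3[a3],
                m3[a0] ^ a1 ^ a2 ^ m2[a3],
            ],
            axis=2,
        )
    else:
        m9, m11, m13, m14 = _MUL[9], _MUL[11], _MUL[13], _MUL[14]
        b = np.stack(
            [
                m14[a0] ^ m11[a1] ^ m13[a2] ^ m9[a3],
                m9[a0] ^ m14[a1] ^ m11[a2] ^ m13[a3],
                m13[a0] ^ m9[a1] ^ m14[a2] ^ m11[a3],
                m11[a0] ^ m13[a1] ^ m9[a2] ^ m14[a3],
            ],
            axis=2,
        )
    return b.reshape(-1, 16)


class AES:
    """AES with a 16-byte (AES-128) or 32-byte (AES-256) key."""

    def __init__(self, key: bytes):
        if len(key) not in (16, 32):
            raise ValueError(f"AES key must be 16 or 32 bytes, got {len(key)}")
        self._round_keys = _expand_key(key)
        self._nr = self._round_keys.shape[0] - 1

    # --- block primitives (vectorized over an (n, 16) uint8 array) ---

    def _encrypt_blocks(self, blocks: np.ndarray) -> np.ndarray:
        state = blocks ^ self._round_keys[0]
        for r in range(1, self._nr):
            state = _SBOX[state][:, _SHIFT]
            state = _mix_columns(state) ^ self._round_keys[r]
        state = _SBOX[state][:, _SHIFT] ^ self._round_keys[self._nr]
        return state

    def _decrypt_blocks(self, blocks: np.ndarray) -> np.ndarray:
        state = blocks ^ self._round_keys[self._nr]
        for r in range(self._nr - 1, 0, -1):
            state = _INV_SBOX[state[:, _INV_SHIFT]] ^ self._round_keys[r]
            state = _mix_columns(state, inverse=True)
        state = _INV_SBOX[state[:, _INV_SHIFT]] ^ self._round_keys[0]
        return state

    def encrypt_block(self, block: bytes) -> bytes:
        if len(block) != 16:
            raise ValueError("block must be 16 bytes")
        arr = np.frombuffer(block, dtype=np.uint8).reshape(1, 16)
        return self._encrypt_blocks(arr).tobytes()

    def decrypt_block(self, block: bytes) -> bytes:
        if len(block) != 16:
            raise ValueError("block must be 16 bytes")
        arr = np.frombuffer(block, dtype=np.uint8).reshape(1, 16)
        return self._decrypt_blocks(arr).tobytes()

    # --- CTR mode (en/decryption are the same operation) ---

    def ctr_xor(self, iv: bytes, data: bytes) -> bytes:
        """XOR ``data`` with the CTR keystream for the 16-byte initial
        counter block ``iv`` (incremented as a big-endian 128-bit integer)."""
        if len(iv) != 16:
            raise ValueError("CTR initial counter block must be 16 bytes")
        if not data:
            return b""
        nblocks = (len(data) + 15) // 16
        base = int.from_bytes(iv, "big")
        counters = np.empty((nblocks, 16), dtype=np.uint8)
        for i in range(nblocks):
            counters[i] = np.frombuffer(
                ((base + i) % (1 << 128)).to_bytes(16, "big"), dtype=np.uint8
            )
        stream = self._encrypt_blocks(counters).tobytes()[: len(data)]
        return bytes(a ^ b for a, b in zip(data, stream)) if len(data) < 1024 else (
            np.frombuffer(data, dtype=np.uint8)
            ^ np.frombuffer(stream, dtype=np.uint8)
        ).tobytes()

    # --- CBC mode ---

    def cbc_encrypt(self, iv: bytes, plaintext: bytes) -> bytes:
        if len(iv) != 16:
            raise ValueError("CBC IV must be 16 bytes")
        if len(plaintext) % 16 != 0:
            raise ValueError("CBC plaintext must be a multiple of 16 bytes (pad first)")
        prev = np.frombuffer(iv, dtype=np.uint8)
        blocks = np.frombuffer(plaintext, dtype=np.uint8).reshape(-1, 16)
        out = np.empty_like(blocks)
        for i in range(blocks.shape[0]):
            prev = self._encrypt_blocks((blocks[i] ^ prev).reshape(1, 16))[0]
            out[i] = prev
        return out.tobytes()

    def cbc_decrypt(self, iv: bytes, ciphertext: bytes) -> bytes:
        if len(iv) != 16:
            raise ValueError("CBC IV must be 16 bytes")
        if not ciphertext or len(ciphertext) % 16 != 0:
            raise ValueError("CBC ciphertext must be a non-empty multiple of 16 bytes")
        blocks = np.frombuffer(ciphertext, dtype=np.uint8).reshape(-1, 16)
        decrypted = self._decrypt_blocks(blocks)
        prev = np.vstack(
            [np.frombuffer(iv, dtype=np.uint8).reshape(1, 16), blocks[:-1]]
        )
        return (decrypted ^ prev).tobytes()


def pkcs7_pad(data: bytes, block: int = 16) -> bytes:
    n = block - (len(data) % block)
    return data + bytes([n]) * n


def pkcs7_unpad(data: bytes, block: int = 16) -> bytes:
    if not data or len(data) % block != 0:
        raise ValueError("invalid padded length")
    n = data[-1]
    if not 1 <= n <= block or data[-n:] != bytes([n]) * n:
        raise ValueError("invalid padding")
    return data[:-n]
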