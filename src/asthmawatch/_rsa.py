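"""RSA key generation and OAEP (SHA-256) encryption for key wrapping.

Used solely to wrap the per-envelope symmetric key; payloads are always a
single short key, far below the OAEP message limit.  Prime generation uses
Miller-Rabin with 40 rounds; keys default to 2048 bits.  Validated in the
test suite by round-trip and wrong-key behavior.
"""

from __future__ import annotations

import hashlib
import random
import secrets
from dataclasses import dataclass

__all__ = [
    "RSAPublicKey",
    "RSAPrivateKey",
    "DecryptionError",
    "generate_keypair",
    "oaep_encrypt",
    "oaep_decrypt",
]

_HASH = hashlib.sha256
_HLEN = 32


class DecryptionError(ValueError):
    """OAEP decryption failed (wrong key or corrupt ciphertext)."""


@dataclass(frozen=True)
class RSAPublicKey:
    n: int
    e: int

    @property
    def byte_length(self) -> int:
        return (self.n.bit_length() + 7) // 8


@dataclass(frozen=True)
class RSAPrivateKey:
    n: int
    e: int
    d: int
    p: int
    q: int

    @property
    def public_key(self) -> RSAPublicKey:
        return RSAPublicKey(n=self.n, e=self.e)

    @property
    def byte_length(self) -> int:
        return (self.n.bit_length() + 7) // 8


_SMALL_PRIMES = [3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61, 67]


def _is_probable_prime(n: int, rng: random.Random, rounds: int = 40) -> bool:
    if n < 2:
        return False
    for p in _SMALL_PRIMES:
        if n % p == 0:
            return n == p
    d, r = n - 1, 0
    while d % 2 == 0:
        d //= 2
        r += 1
    for _ in range(rounds):
        a = rng.randrange(2, n - 1)
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(r - 1):
            x = (x * x) % n
            if x == n - 1:
                break
        else:
            return False
    return True


def _gen_prime(bits: int, rng: random.Random) -> int:
    while True:
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | (1 << (bits - 2)) | 1
        if _is_probable_prime(cand, rng):
            return cand


def generate_keypair(bits: int = 2048, e: int = 65537, rng: random.Random | None = None) -> RSAPrivateKey:
    """Generate an RSA keypair.

    ``rng`` defaults to a system-entropy source; pass a seeded
    ``random.Random`` only for reproducible test keys.
    """
    if bits < 512:
        raise ValueError("RSA modulus must be at least 512 bits")
    if rng is None:
        rng = random.SystemRandom()
    half = bits // 2
    while True:
        p = _gen_prime(half, rng)
        q = _gen_prime(bits - half, rng)
        if p == q:
            continue
        n = p * q
        if n.bit_length() != bits:
            continue
        phi = (p - 1) * (q - 1)
        try:
            d = pow(e, -1, phi)
        except ValueError:
            continue
        return RSAPrivateKey(n=n, e=e, d=d, p=p, q=q)


def _mgf1(seed: bytes, length: int) -> bytes:
    out = b""
    counter = 0
    while len(out) < length:
        out += _HASH(seed + counter.to_bytes(4, "big")).digest()
        counter += 1
    return out[:length]


def _xor(a: bytes, b: bytes) -> bytes:
    return bytes(x ^ y for x, y in zip(a, b))


def oaep_encrypt(pub: RSAPublicKey, message: bytes, label: bytes = b"") -> bytes:
    """RSAES-OAEP (SHA-256) encryption of a short message."""
    k = pub.byte_length
    if len(message) > k - 2 * _HLEN - 2:
        raise ValueError(f"message too long for OAEP with a {k * 8}-bit modulus")
    lhash = _HASH(label).digest()
    ps = b"\x00" * (k - len(message) - 2 * _HLEN - 2)
    db = lhash + ps + b"\x01" + message
    seed = secrets.token_bytes(_HLEN)
    masked_db = _xor(db, _mgf1(seed, k - _HLEN - 1))
    masked_seed = _xor(seed, _mgf1(masked_db, _HLEN))
    em = b"\x00" + masked_seed + masked_db
    c = pow(int.from_bytes(em, "big"), pub.e, pub.n)
    return c.to_bytes(k, "big")


def oaep_decrypt(priv: RSAPrivateKey, ciphertext: bytes, label: bytes = b"") -> bytes:
    """RSAES-OAEP decryption; raises :class:`DecryptionError` on any failure."""
    k = priv.byte_length
    if len(ciphertext) != k or k < 2 * _HLEN + 2:
        raise DecryptionError("ciphertext length inconsistent with key modulus")
    c = int.from_bytes(ciphertext, "big")
    if c >= priv.n:
        raise DecryptionError("ciphertext representative out of range")
    em = pow(c, priv.d, priv.n).to_bytes(k, "big")
    y, masked_seed, masked_db = em[0], em[1 : 1 + _HLEN], em[1 + _HLEN :]
    seed = _xor(masked_seed, _mgf1(masked_db, _HLEN))
    db = _xor(masked_db, _mgf1(seed, k - _HLEN - 1))
    lhash = _HASH(label).digest()
    # locate the 0x01 separator after the zero padding
    sep = db.find(b"\x01", _HLEN)
    ps_ok = sep != -1 and all(b == 0 for b in db[_HLEN:sep])
    if y != 0 or db[:_HLEN] != lhash or not ps_ok:
        raise DecryptionError("OAEP decoding failed")
    return db[sep + 1 :]
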