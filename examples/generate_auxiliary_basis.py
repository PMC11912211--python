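"""Generate GEN-Xn auxiliary bases for a toy s/p/d orbital basis.

The orbital basis spans exponents 0.1..50 with a d polarization function at
0.8, so the even-tempered ladder is anchored at alpha0 = 2 x 0.8 = 1.6 and
covers the product interval [0.2, 100] with progression factor beta = 6 - n.
"""

from auxgen import generate_genx, toy_obs, write_aux_basis

obs = toy_obs("O")
for n in (2, 3, 4):
    aux = generate_genx(obs, n)
    print(f"GEN-X{n}: beta={aux.beta:.0f}  alpha0={aux.alpha0}  "
          f"{aux.n_alpha} sets / {aux.n_functions} functions")
    print(write_aux_basis(aux))

# Each line "k  L  alpha" is one shared-exponent set: all Hermite functions
# with angular index 0..L on the exponent alpha, i.e. (L+1)(L+2)(L+3)/6
# functions.  Larger n means a denser ladder and a bigger, more accurate basis.
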