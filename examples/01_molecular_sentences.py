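"""Turn SMILES strings into molecular sentences.

Each heavy atom contributes a radius-0 identifier (its hashed atomic
invariants) and, where its neighborhood grows, a radius-1 identifier covering
the atom plus its immediate bonds.  After removing duplicate environments the
identifiers, sorted by canonical atom order and radius, form the molecule's
"sentence".
"""

from molsent import generate_sentence, parse_smiles

for smiles in ["CCCN(=O)=O", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O"]:
    graph = parse_smiles(smiles)
    sentence = generate_sentence(smiles, max_radius=1)
    print(f"{smiles:25s} heavy atoms={graph.n_atoms:2d} tokens={len(sentence):2d}")
    print("  ", sentence.as_text())

# Two spellings of one molecule give the same sentence:
a = generate_sentence("C1=CC=CC=C1").tokens
b = generate_sentence("c1ccccc1").tokens
print("kekulized and aromatic benzene agree:", a == b)
# The token counts equal the number of unique circular substructures per
# molecule; 1-nitropropane has 4 unique atom types + 5 unique radius-1
# neighborhoods = 9 tokens.
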