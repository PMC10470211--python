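{
 "AXT": {
  "description": "Astaxanthin (C40H52O4): two beta-end rings with 3-hydroxy/4-keto substitution flanking a conjugated C7..C7' polyene; standard carotenoid numbering with primes for the second half.",
  "atoms": [
   "C1",
   "C2",
   "C3",
   "C4",
   "C5",
   "C6",
   "C7",
   "C8",
   "C9",
   "C10",
   "C11",
   "C12",
   "C13",
   "C14",
   "C15",
   "C16",
   "C17",
   "C18",
   "C19",
   "C20",
   "O3",
   "O4",
   "C1'",
   "C2'",
   "C3'",
   "C4'",
   "C5'",
   "C6'",
   "C7'",
   "C8'",
   "C9'",
   "C10'",
   "C11'",
   "C12'",
   "C13'",
   "C14'",
   "C15'",
   "C16'",
   "C17'",
   "C18'",
   "C19'",
   "C20'",
   "O3'",
   "O4'"
  ],
  "bonds": [
   [
    "C1",
    "C2",
    1
   ],
   [
    "C2",
    "C3",
    1
   ],
   [
    "C3",
    "C4",
    1
   ],
   [
    "C4",
    "C5",
    1
   ],
   [
    "C5",
    "C6",
    2
   ],
   [
    "C6",
    "C1",
    1
   ],
   [
    "C1",
    "C16",
    1
   ],
   [
    "C1",
    "C17",
    1
   ],
   [
    "C5",
    "C18",
    1
   ],
   [
    "C3",
    "O3",
    1
   ],
   [
    "C4",
    "O4",
    2
   ],
   [
    "C6",
    "C7",
    1
   ],
   [
    "C7",
    "C8",
    2
   ],
   [
    "C8",
    "C9",
    1
   ],
   [
    "C9",
    "C10",
    2
   ],
   [
    "C10",
    "C11",
    1
   ],
   [
    "C11",
    "C12",
    2
   ],
   [
    "C12",
    "C13",
    1
   ],
   [
    "C13",
    "C14",
    2
   ],
   [
    "C14",
    "C15",
    1
   ],
   [
    "C9",
    "C19",
    1
   ],
   [
    "C13",
    "C20",
    1
   ],
   [
    "C1'",
    "C2'",
    1
   ],
   [
    "C2'",
    "C3'",
    1
   ],
   [
    "C3'",
    "C4'",
    1
   ],
   [
    "C4'",
    "C5'",
    1
   ],
   [
    "C5'",
    "C6'",
    2
   ],
   [
    "C6'",
    "C1'",
    1
   ],
   [
    "C1'",
    "C16'",
    1
   ],
   [
    "C1'",
    "C17'",
    1
   ],
   [
    "C5'",
    "C18'",
    1
   ],
   [
    "C3'",
    "O3'",
    1
   ],
   [
    "C4'",
    "O4'",
    2
   ],
   [
    "C6'",
    "C7'",
    1
   ],
   [
    "C7'",
    "C8'",
    2
   ],
   [
    "C8'",
    "C9'",
    1
   ],
   [
    "C9'",
    "C10'",
    2
   ],
   [
    "C10'",
    "C11'",
    1
   ],
   [
    "C11'",
    "C12'",
    2
   ],
   [
    "C12'",
    "C13'",
    1
   ],
   [
    "C13'",
    "C14'",
    2
   ],
   [
    "C14'",
    "C15'",
    1
   ],
   [
    "C9'",
    "C19'",
    1
   ],
   [
    "C13'",
    "C20'",
    1
   ],
   [
    "C15",
    "C15'",
    2
   ]
  ],
  "polyene_path": [
   "C7",
   "C8",
   "C9",
   "C10",
   "C11",
   "C12",
   "C13",
   "C14",
   "C15",
   "C15'",
   "C14'",
   "C13'",
   "C12'",
   "C11'",
   "C10'",
   "C9'",
   "C8'",
   "C7'"
  ],
  "end_rings": {
   "beta": [
    "C1",
    "C2",
    "C3",
    "C4",
    "C5",
    "C6",
    "C16",
    "C17",
    "C18",
    "O3",
    "O4"
   ],
   "beta_prime": [
    "C1'",
    "C2'",
    "C3'",
    "C4'",
    "C5'",
    "C6'",
    "C16'",
    "C17'",
    "C18'",
    "O3'",
    "O4'"
   ]
  },
  "torsions": {
   "C5-C6-C7-C8": [
    "C5",
    "C6",
    "C7",
    "C8"
   ],
   "C5'-C6'-C7'-C8'": [
    "C5'",
    "C6'",
    "C7'",
    "C8'"
   ]
  }
 },
 "MXT": {
  "description": "Mytiloxanthin (C40H54O4), reconstructed template: one beta-end ring (3-hydroxy), a C7-C8 triple bond, a C8' enolic hydroxyl on the polyene chain, and a kappa (cyclopentane) end ring carrying the C3' hydroxyl and C6' keto groups. Atom labels follow the standard carotenoid numbering used in the literature; depositions may use a different dialect, absorbed by name normalization and the fractional matching rule.",
  "atoms": [
   "C1",
   "C2",
   "C3",
   "C4",
   "C5",
   "C6",
   "C7",
   "C8",
   "C9",
   "C10",
   "C11",
   "C12",
   "C13",
   "C14",
   "C15",
   "C16",
   "C17",
   "C18",
   "C19",
   "C20",
   "O3",
   "C1'",
   "C2'",
   "C3'",
   "C4'",
   "C5'",
   "C6'",
   "C7'",
   "C8'",
   "C9'",
   "C10'",
   "C11'",
   "C12'",
   "C13'",
   "C14'",
   "C15'",
   "C16'",
   "C17'",
   "C18'",
   "C19'",
   "C20'",
   "O3'",
   "O6'",
   "O8'"
  ],
  "bonds": [
   [
    "C1",
    "C2",
    1
   ],
   [
    "C2",
    "C3",
    1
   ],
   [
    "C3",
    "C4",
    1
   ],
   [
    "C4",
    "C5",
    1
   ],
   [
    "C5",
    "C6",
    2
   ],
   [
    "C6",
    "C1",
    1
   ],
   [
    "C1",
    "C16",
    1
   ],
   [
    "C1",
    "C17",
    1
   ],
   [
    "C5",
    "C18",
    1
   ],
   [
    "C3",
    "O3",
    1
   ],
   [
    "C6",
    "C7",
    1
   ],
   [
    "C7",
    "C8",
    3
   ],
   [
    "C8",
    "C9",
    1
   ],
   [
    "C9",
    "C10",
    2
   ],
   [
    "C10",
    "C11",
    1
   ],
   [
    "C11",
    "C12",
    2
   ],
   [
    "C12",
    "C13",
    1
   ],
   [
    "C13",
    "C14",
    2
   ],
   [
    "C14",
    "C15",
    1
   ],
   [
    "C9",
    "C19",
    1
   ],
   [
    "C13",
    "C20",
    1
   ],
   [
    "C15",
    "C15'",
    2
   ],
   [
    "C15'",
    "C14'",
    1
   ],
   [
    "C14'",
    "C13'",
    2
   ],
   [
    "C13'",
    "C12'",
    1
   ],
   [
    "C12'",
    "C11'",
    2
   ],
   [
    "C11'",
    "C10'",
    1
   ],
   [
    "C10'",
    "C9'",
    2
   ],
   [
    "C9'",
    "C8'",
    1
   ],
   [
    "C8'",
    "C7'",
    2
   ],
   [
    "C8'",
    "O8'",
    1
   ],
   [
    "C9'",
    "C19'",
    1
   ],
   [
    "C13'",
    "C20'",
    1
   ],
   [
    "C1'",
    "C2'",
    1
   ],
   [
    "C2'",
    "C3'",
    1
   ],
   [
    "C3'",
    "C4'",
    1
   ],
   [
    "C4'",
    "C5'",
    1
   ],
   [
    "C5'",
    "C1'",
    1
   ],
   [
    "C1'",
    "C16'",
    1
   ],
   [
    "C1'",
    "C17'",
    1
   ],
   [
    "C5'",
    "C18'",
    1
   ],
   [
    "C3'",
    "O3'",
    1
   ],
   [
    "C5'",
    "C6'",
    1
   ],
   [
    "C6'",
    "O6'",
    2
   ],
   [
    "C6'",
    "C7'",
    1
   ]
  ],
  "polyene_path": [
   "C7",
   "C8",
   "C9",
   "C10",
   "C11",
   "C12",
   "C13",
   "C14",
   "C15",
   "C15'",
   "C14'",
   "C13'",
   "C12'",
   "C11'",
   "C10'",
   "C9'",
   "C8'",
   "C7'"
  ],
  "end_rings": {
   "beta": [
    "C1",
    "C2",
    "C3",
    "C4",
    "C5",
    "C6",
    "C16",
    "C17",
    "C18",
    "O3"
   ],
   "kappa": [
    "C1'",
    "C2'",
    "C3'",
    "C4'",
    "C5'",
    "C6'",
    "C16'",
    "C17'",
    "C18'",
    "O3'",
    "O6'"
   ]
  },
  "torsions": {
   "C5-C6-C7-C8": [
    "C5",
    "C6",
    "C7",
    "C8"
   ],
   "C5'-C6'-C7'-C8'": [
    "C5'",
    "C6'",
    "C7'",
    "C8'"
   ]
  }
 }
}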