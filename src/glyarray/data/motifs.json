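{
 "version": "1.0",
 "motifs": [
  {
   "name": "Lactose core",
   "pattern": "Galb-4Glc",
   "anchor": "anywhere"
  },
  {
   "name": "Type 2 LacNAc",
   "pattern": "Galb-4GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Type 1 LacNAc",
   "pattern": "Galb-3GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "LacdiNAc",
   "pattern": "GalNAcb-4GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "alpha2-3 sialyl galactose",
   "pattern": "NeuAca-3Gal",
   "anchor": "anywhere"
  },
  {
   "name": "alpha2-6 sialyl galactose",
   "pattern": "NeuAca-6Gal",
   "anchor": "anywhere"
  },
  {
   "name": "alpha2-8 disialyl",
   "pattern": "NeuAca-8NeuAc",
   "anchor": "anywhere"
  },
  {
   "name": "alpha2-6 sialyl GlcNAc",
   "pattern": "NeuAca-6GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Sialyl-Tn",
   "pattern": "NeuAca-6GalNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Lewis x",
   "pattern": "Galb-4(Fuca-3)GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Lewis a",
   "pattern": "Galb-3(Fuca-4)GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Lewis y",
   "pattern": "Fuca-2Galb-4(Fuca-3)GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Lewis b",
   "pattern": "Fuca-2Galb-3(Fuca-4)GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Sialyl-Lewis x",
   "pattern": "NeuAca-3Galb-4(Fuca-3)GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Sialyl-Lewis a",
   "pattern": "NeuAca-3Galb-3(Fuca-4)GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Blood group H type 2",
   "pattern": "Fuca-2Galb-4GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Blood group H type 1",
   "pattern": "Fuca-2Galb-3GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Blood group H disaccharide",
   "pattern": "Fuca-2Gal",
   "anchor": "anywhere"
  },
  {
   "name": "Blood group A",
   "pattern": "GalNAca-3(Fuca-2)Gal",
   "anchor": "anywhere"
  },
  {
   "name": "Blood group B",
   "pattern": "Gala-3(Fuca-2)Gal",
   "anchor": "anywhere"
  },
  {
   "name": "Linear B type 2",
   "pattern": "Gala-3Galb-4GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "alpha-Gal epitope",
   "pattern": "Gala-3Gal",
   "anchor": "anywhere"
  },
  {
   "name": "Galabiose",
   "pattern": "Gala-4Gal",
   "anchor": "anywhere"
  },
  {
   "name": "Globotriose (Gb3)",
   "pattern": "Gala-4Galb-4Glc",
   "anchor": "anywhere"
  },
  {
   "name": "Isoglobotriose",
   "pattern": "Gala-3Galb-4Glc",
   "anchor": "anywhere"
  },
  {
   "name": "3'-sialyllactose",
   "pattern": "NeuAca-3Galb-4Glc",
   "anchor": "anywhere"
  },
  {
   "name": "6'-sialyllactose",
   "pattern": "NeuAca-6Galb-4Glc",
   "anchor": "anywhere"
  },
  {
   "name": "3'-sialyl LacNAc",
   "pattern": "NeuAca-3Galb-4GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "6'-sialyl LacNAc",
   "pattern": "NeuAca-6Galb-4GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "T antigen (core 1)",
   "pattern": "Galb-3GalNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Tn antigen",
   "pattern": "GalNAca",
   "anchor": "reducing_end"
  },
  {
   "name": "O-glycan core 2",
   "pattern": "Galb-3(GlcNAcb-6)GalNAc",
   "anchor": "anywhere"
  },
  {
   "name": "O-glycan core 3",
   "pattern": "GlcNAcb-3GalNAc",
   "anchor": "anywhere"
  },
  {
   "name": "O-glycan core 4",
   "pattern": "GlcNAcb-3(GlcNAcb-6)GalNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Sialyl-T",
   "pattern": "NeuAca-3Galb-3GalNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Disialyl-T",
   "pattern": "NeuAca-3Galb-3(NeuAca-6)GalNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Chitobiose",
   "pattern": "GlcNAcb-4GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Chitotriose",
   "pattern": "GlcNAcb-4GlcNAcb-4GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "N-glycan trimannosyl core",
   "pattern": "Mana-3(Mana-6)Manb-4GlcNAcb-4GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Man alpha1-2 Man",
   "pattern": "Mana-2Man",
   "anchor": "anywhere"
  },
  {
   "name": "Man alpha1-3 Man",
   "pattern": "Mana-3Man",
   "anchor": "anywhere"
  },
  {
   "name": "Man alpha1-6 Man",
   "pattern": "Mana-6Man",
   "anchor": "anywhere"
  },
  {
   "name": "Core fucose",
   "pattern": "Fuca-6GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Fuc alpha1-3 GlcNAc",
   "pattern": "Fuca-3GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Fuc alpha1-4 GlcNAc",
   "pattern": "Fuca-4GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "i antigen unit",
   "pattern": "Galb-4GlcNAcb-3Gal",
   "anchor": "anywhere"
  },
  {
   "name": "I antigen branch",
   "pattern": "Galb-4GlcNAcb-3(Galb-4GlcNAcb-6)Gal",
   "anchor": "anywhere"
  },
  {
   "name": "GlcNAc beta1-3 Gal",
   "pattern": "GlcNAcb-3Gal",
   "anchor": "anywhere"
  },
  {
   "name": "GlcNAc beta1-6 Gal",
   "pattern": "GlcNAcb-6Gal",
   "anchor": "anywhere"
  },
  {
   "name": "Ganglio GalNAc beta1-4 Gal",
   "pattern": "GalNAcb-4Gal",
   "anchor": "anywhere"
  },
  {
   "name": "Asialo-GM1 terminal",
   "pattern": "Galb-3GalNAcb-4Gal",
   "anchor": "anywhere"
  },
  {
   "name": "GM1 terminal",
   "pattern": "Galb-3GalNAcb-4(NeuAca-3)Gal",
   "anchor": "anywhere"
  },
  {
   "name": "GD3 terminal",
   "pattern": "NeuAca-8NeuAca-3Gal",
   "anchor": "anywhere"
  },
  {
   "name": "Cellobiose unit",
   "pattern": "Glcb-4Glc",
   "anchor": "anywhere"
  },
  {
   "name": "Maltose unit",
   "pattern": "Glca-4Glc",
   "anchor": "anywhere"
  },
  {
   "name": "Isomaltose unit",
   "pattern": "Glca-6Glc",
   "anchor": "anywhere"
  },
  {
   "name": "Laminaribiose unit",
   "pattern": "Glcb-3Glc",
   "anchor": "anywhere"
  },
  {
   "name": "Hyaluronan unit",
   "pattern": "GlcAb-3GlcNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Chondroitin unit",
   "pattern": "GlcAb-3GalNAc",
   "anchor": "anywhere"
  },
  {
   "name": "Xylobiose unit",
   "pattern": "Xylb-4Xyl",
   "anchor": "anywhere"
  }
 ]
}
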