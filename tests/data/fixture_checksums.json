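{
 "ALDO.rxn": "b1d621da19c81f38acd4bb94a56949d98d55211556a5cfad2268947fcd2ec6c4",
 "ENO.rxn": "61e20067e94b41d2f6449d8721a0fa94db09a291acb79ab3859c2eef8018158a",
 "FUM.rxn": "48af9b65edb315889ef969435e083a25a55ece8864ff54d1723d36878b1877d3",
 "GAD.rxn": "8a488f52df2df22d1d5cd5f590086661132b3280e4df399fbd1b02d7cb89c691",
 "GAPDH.rxn": "6ad0ac0b067dd031b6ffb97ce6ff4f33d5ac3252083f116b76b66e69732ba456",
 "GLS.rxn": "4acf3d340d464d104b8f177faf5490021ecf44fdcb85e906e701718935ba9989",
 "HK.rxn": "ed5dead23d0d8f940bb6a7cbc6c237d3a30c50cac156075e894eb6265c82d389",
 "HK_ATP.rxn": "28c9ddfa8f968aa655947a2914c9a2f30a27f763798f24146b347480a629874d",
 "PDH.rxn": "b43a1582e054f0a7c671f15d352d2ea84ae25fb73880c5ed9dcd244e1b1eb135",
 "PFK.rxn": "fdef3576631ece74466a6194f93255ecc44971c22f9073b09200646cf9abcd62",
 "PGI.rxn": "9a0884193b1c92599af4d6f1e61b728fee74f3996ea7677f4a8c46c9667f5a41",
 "PGK.rxn": "122588fd1bbb1c0b2e0c053d39b55213a43f74ec09bedd249d908f37fe248586",
 "PGM.rxn": "cf61bcf926be05cde942786d0cb73bc7c9843906e2880742bfd40979f76c3d66",
 "PK.rxn": "d115fe9033da68c0dd696760bbce372c010f742ab5c6419b1f78d00d6bbe82e4",
 "PYRT.rxn": "43f1b2770483f3755df6854e2e8ff0c3287b65187051ae7a2419900c78fe68ba",
 "THL.rxn": "a3f5990440e28d8649f685c10cc86ae94c9e805518abf2fc7a3c696b9d0eb632",
 "TPI.rxn": "f983570e1d04e41fe37e7f52597e2c11fc5a16f3b29f9b68610ab2d9a9c71bd8",
 "aliases.csv": "4036ed0ddd75a7dd4faa2dc000d4688f007a83ba4ddf349131774723daff3b5a",
 "fumarase.csv": "3b971096da3819ffd3dee50ca95ce35c3a8c59de6d2d4ad4a4e98b743fe61c85",
 "glutamine_gaba_custom.csv": "d9a26a3df55adb63be3c7a19027c2136c12339054f56b8a4fae3d74960c8742a",
 "glutamine_gaba_store.csv": "ebe26242f5f39a7f28271add53d97a7300bf4a2b14c513c51258188bc9ad8304",
 "hexokinase_full.csv": "cab316cfe733ad6d473d096805472adc380f78cca3600dbdd0b43d40b5afd25e",
 "index.csv": "faae51064e4e81940dbb74c165d86ba6e384befe98c387e41222977ef8766e7f",
 "metabolites.csv": "bb07fa6491a929b6a725dd9ae5e99c49f5143d33a9ffb6e7b52544a4682a57eb",
 "molecules/ADP.mol": "c2d6448cc37d3eca26f9a1898ff989f64af25607ec506cc05c15bc23149101b1",
 "molecules/ATP.mol": "5f29060c5f1e8f7f73209b3228587065ed0f25d6f16d81cb159824d60b24a795",
 "molecules/BPG13.mol": "b0db723180072f413c80fd4db097d7f6fe04b8e60820f05e163d160eec84b36c",
 "molecules/CO2.mol": "f32d5c0747f1e66f2af4a8a028a7c5b7d311277ab701b8d9691585a06f7c10f7",
 "molecules/DHAP.mol": "49760e32849a3589bd651ef7622118d4222a15f106e5c7b75d5ae2ad45f831e6",
 "molecules/F16BP.mol": "24ced747523e4a8c190cdd1658eb4674193906d291db3e6da7bd141386580398",
 "molecules/F6P.mol": "c7717f0bb66878b0461f3def8d086fc1e3ed7a9eca017336ca60723896d3c2f2",
 "molecules/G6P.mol": "74a47db1fdf6e6e844a7d612b673f34fecb953d7f81247ce759da6ac3f39e14c",
 "molecules/GABA.mol": "c5074014962e455d1c7e33b110b322039f35db884df6347b917c04fa91eec2b5",
 "molecules/GAP.mol": "563787a48f93f828a5766c3e172e791b1368813f503d012ead9e1c52a03c4dcd",
 "molecules/PEP.mol": "c62916a8e3fd00393fdc2cf0b5334066092c59e7cd5643c731b4650834d183d8",
 "molecules/PG2.mol": "251b0f62841e0afcacfbd235e4a0055b62c0f10594de7f6bfb1ac6c14e3b27e1",
 "molecules/PG3.mol": "71262ef4dc8b6b53b92ea6d01f085d12becd9ae2a9153d6bf26c05762ad63064",
 "molecules/acetoacetate.mol": "12be634226588473d271a573b2bffa7024261ac335f11eb7e5a032f5b93829f2",
 "molecules/acetyl-CoA.mol": "677c74f1b08ca7423cbefd4a1ea8e01b56009b6eadec54e334e741bf3f41590d",
 "molecules/ammonia.mol": "87492317945e114ee8b4af1c08cdb51d8c15cd61e23d9f4a477eb694ffc45d4f",
 "molecules/benzene.mol": "db2da8c6ddbef95f246b5e567020e40e5be504770eaadef3296dbd0d35f56099",
 "molecules/fumarate.mol": "76c497634c4148da83016d15c1e83f507f257000c907cf3a61121c50ed6a2644",
 "molecules/glucose.mol": "e2f8073435752e38df642d7604a57cc7483249f3b550d558b467fec408996c2a",
 "molecules/glutamate.mol": "4197eea616ba36be58976f9e3b9bb9b23204ab757c9bc9dcefff26c7bfe90fc3",
 "molecules/glutamine.mol": "f93ae409c2c41a68e0646105c545a713fe2a235c413de8feeff4648d825b650c",
 "molecules/malate.mol": "d44bbf4748af599443a61af9eca97991e985575f5e21abae30df1c0aa9b9c444",
 "molecules/pyruvate.mol": "6cb7698c1ec1b5ebeec1e65583f6e642107101e0c0d1a2196574971c20a905e2",
 "molecules/water.mol": "b4cbd4ce9c200225f38614ee43f169e97f11a507f4aa070f88b5d8d352af9a9e",
 "thiolase.csv": "9741d87e44a5bc30115b445c3e4438e605c90917f31b6c55537f04d3701ee6e3",
 "toy_glycolysis.csv": "56518b8a6aa0d9c8b3b92b1904444dabc48094b8b8e78ed13eb49fc6dc697b0c"
}
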